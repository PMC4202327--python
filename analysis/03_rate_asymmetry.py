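"""Clock vs free-rate tests on simulated duplicate triplets.

Simulates a small cohort of protein triplets — a third of the pairs with a
3x accelerated dup1 branch — runs the JTT clock/free likelihood-ratio
tests with Benjamini–Hochberg adjustment, and calls accelerated copies at
Q < 0.05.  Also reports the type-I-error calibration of the test.
"""

from pathlib import Path

import pandas as pd

from dupreloc.aamodels import jtt_model
from dupreloc.calibration import clock_lrt_type1_error
from dupreloc.likelihood import clock_test_cohort
from dupreloc.simulate import TripletTree, simulate_aa_triplet

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SEED = 0
N_PAIRS, N_ASYM, N_SITES = 30, 10, 800

model = jtt_model()
alignments = {}
for i in range(N_PAIRS):
    b1 = 0.24 if i < N_ASYM else 0.08
    tree = TripletTree(b1, 0.08, 0.25)
    alignments[f"pair{i + 1:03d}"] = simulate_aa_triplet(
        tree, model, N_SITES, seed=[SEED, i])

results = clock_test_cohort(alignments, model, n_starts=2)
df = pd.DataFrame([{
    "pair_id": r.pair_id, "lnL_clock": r.lnl_clock, "lnL_free": r.lnl_free,
    "b1": r.b1, "b2": r.b2, "b3": r.b3, "two_delta_L": r.lrt.two_delta_l,
    "P": r.lrt.p_value, "Q": r.q_value, "accelerated_copy": r.accelerated_copy,
} for r in results])
df.to_csv(OUT / "rate_tests.tsv", sep="\t", index=False, float_format="%.6g")

called = (df["accelerated_copy"] != "none").sum()
true_pos = (df["accelerated_copy"][:N_ASYM] == "gene1").sum()
print(f"simulated {N_PAIRS} triplets ({N_ASYM} with a 3x-accelerated dup1 branch,"
      f" {N_SITES} sites)")
print(f"significant at Q<0.05: {called}; correct accelerated-copy calls among"
      f" the {N_ASYM} asymmetric pairs: {true_pos}")

calib = clock_lrt_type1_error(n_reps=200, n_sites=1000, seed=SEED)
print(f"type-I error at alpha=0.05 over {calib.n} clock-simulated triplets:"
      f" {calib.value:.3f}")
print(f"wrote {OUT / 'rate_tests.tsv'}")
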