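"""Branch-site test of positive selection on an accelerated duplicate.

Simulates a codon triplet in which 15% of sites evolve under omega = 6 on
the dup1 branch only, fits branch-site Model A with dup1 as foreground
(alternative omega2 free vs null omega2 = 1), and locates the selected
sites by Bayes Empirical Bayes at posterior > 0.95.
"""

from pathlib import Path

from dupreloc.branch_site import beb_site_posteriors, fit_branch_site
from dupreloc.likelihood import lrt
from dupreloc.simulate import TripletTree, simulate_codon_triplet

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SEED = 0
aln = simulate_codon_triplet(
    TripletTree(0.2, 0.2, 0.5), kappa=2.0,
    site_classes=[(0.85, (0.1, 0.1, 0.1)), (0.15, (6.0, 0.1, 0.1))],
    n_codons=500, seed=SEED)

fit = fit_branch_site(aln, "dup1", n_starts=2)
sites = beb_site_posteriors(fit, aln)
true_sites = {int(i) + 1 for i in (aln.site_classes == 1).nonzero()[0]}
flagged = {s.position for s in sites}

lines = [
    "branch-site Model A on a simulated selection triplet",
    f"foreground: dup1; {len(true_sites)} of {aln.n_codons} codons simulated"
    " under omega=6 on the foreground branch",
    f"alternative: lnL = {fit.lnl_alt:.2f} ({fit.n_params_alt} free parameters),"
    f" omega2 = {fit.omega2:.3f}",
    f"null:        lnL = {fit.lnl_null:.2f} ({fit.n_params_null} free parameters),"
    f" omega2 = {fit.null_omega2:.3f}",
    f"2dL = {fit.lrt.two_delta_l:.2f}, chi-square(1) P = {fit.lrt.p_value:.3g}",
    f"site classes: p0 = {fit.p0:.3f}, p1 = {fit.p1:.3f},"
    f" p2+p3 = {fit.p2_plus_p3:.3f}; omega0 = {fit.omega0:.3f}",
    "BEB sites (posterior > 0.95): " + ", ".join(str(s) for s in sites),
    f"true positives among flagged: {len(flagged & true_sites)}/{len(flagged)}",
]
text = "\n".join(lines)
print(text)
(OUT / "branch_site.txt").write_text(text + "\n")

ref = lrt(-6306.97, -6311.76)
print(f"\npublished-likelihood arithmetic check: 2dL = {ref.two_delta_l:.2f},"
      f" P = {ref.p_value:.3g}")
print(f"wrote {OUT / 'branch_site.txt'}")
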