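"""Simulation studies that validate the statistical machinery.

These are the package's own checks of its estimators and tests, run at
desk scale: type-I error of the clock LRT, accuracy of accelerated-copy
identification, agreement of the ML and counting dN/dS routes, and the
behaviour of the branch-site test and BEB under a null with no positive
selection.  Both the test suite and the reproduction script call these
functions; problem sizes are arguments with the defaults used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aamodels import jtt_model
from .branch_site import beb_site_posteriors, fit_branch_site
from .dnds import ng86_dnds, pairwise_dnds_ml
from .likelihood import clock_test
from .simulate import TripletTree, simulate_aa_triplet, simulate_codon_triplet


@dataclass
class CalibrationResult:
    name: str
    value: float
    n: int
    detail: dict


def clock_lrt_type1_error(n_reps: int = 500, n_sites: int = 1000,
                          b: float = 0.1, b_out: float = 0.3,
                          alpha: float = 0.05, seed: int = 0,
                          n_starts: int = 2) -> CalibrationResult:
    """Rejection rate of the clock LRT on clock-simulated triplets.

    Under the null (b1 = b2) the LRT p-value is asymptotically uniform, so
    the rate should sit near alpha.
    """
    model = jtt_model()
    tree = TripletTree(b, b, b_out)
    rejections = 0
    for i in range(n_reps):
        aln = simulate_aa_triplet(tree, model, n_sites, seed=[seed, i])
        res = clock_test(aln, model, n_starts=n_starts)
        if res.lrt.p_value < alpha:
            rejections += 1
    rate = rejections / n_reps
    return CalibrationResult("clock_lrt_type1_error", rate, n_reps,
                             {"n_sites": n_sites, "alpha": alpha})


def accelerated_copy_accuracy(n_reps: int = 100, n_sites: int = 2000,
                              b_fast: float = 0.3, b_slow: float = 0.1,
                              b_out: float = 0.3, alpha: float = 0.05,
                              seed: int = 0, n_starts: int = 2) -> CalibrationResult:
    """Fraction of significant replicates naming the truly faster copy.

    Simulates b1 = 3 * b2 by default; the accelerated copy is called from
    the longer fitted branch among replicates where the LRT rejects.
    """
    model = jtt_model()
    tree = TripletTree(b_fast, b_slow, b_out)
    n_sig = n_correct = 0
    for i in range(n_reps):
        aln = simulate_aa_triplet(tree, model, n_sites, seed=[seed, 7000 + i])
        res = clock_test(aln, model, n_starts=n_starts)
        if res.lrt.p_value < alpha:
            n_sig += 1
            if res.b1 > res.b2:
                n_correct += 1
    frac = n_correct / n_sig if n_sig else np.nan
    return CalibrationResult("accelerated_copy_accuracy", frac, n_reps,
                             {"n_significant": n_sig, "n_sites": n_sites})


def ml_vs_ng86_agreement(n_reps_per_t: int = 4, n_codons: int = 2000,
                         omega: float = 0.2, kappa: float = 2.0,
                         ts: tuple[float, ...] = (0.1, 0.2, 0.3),
                         seed: int = 0) -> CalibrationResult:
    """Worst relative deviation between ML and NG86 dN and dS estimates
    on pairs simulated at divergences up to t = 0.3."""
    worst = 0.0
    n = 0
    for t in ts:
        tree = TripletTree(t / 2, t / 2, 0.0)
        for i in range(n_reps_per_t):
            aln = simulate_codon_triplet(tree, kappa, [(1.0, (omega,) * 3)],
                                         n_codons=n_codons, seed=[seed, n])
            ml = pairwise_dnds_ml(aln.seqs[0], aln.seqs[1])
            ng = ng86_dnds(aln.seqs[0], aln.seqs[1])
            worst = max(worst, abs(ml.dn - ng.dn) / ng.dn,
                        abs(ml.ds - ng.ds) / ng.ds)
            n += 1
    return CalibrationResult("ml_vs_ng86_max_rel_dev", worst, n,
                             {"n_codons": n_codons, "ts": list(ts)})


def branch_site_null_calibration(n_reps: int = 60, n_codons: int = 200,
                                 alpha: float = 0.05, seed: int = 0,
                                 n_starts: int = 2) -> CalibrationResult:
    """Branch-site LRT rejection rate and BEB false-positive behaviour
    under a null with purifying + neutral classes only.

    Because the null pins omega2 at the boundary, the df=1 chi-square
    reference is conservative: the rejection rate should fall at or below
    alpha, and BEB should flag no site in nearly all replicates.
    """
    tree = TripletTree(0.2, 0.2, 0.5)
    classes = [(0.8, (0.1, 0.1, 0.1)), (0.2, (1.0, 1.0, 1.0))]
    rejections = zero_site_reps = 0
    for i in range(n_reps):
        aln = simulate_codon_triplet(tree, 2.0, classes, n_codons=n_codons,
                                     seed=[seed, 3000 + i])
        fit = fit_branch_site(aln, "dup1", n_starts=n_starts)
        if fit.lrt.p_value < alpha:
            rejections += 1
        sites = beb_site_posteriors(fit, aln)
        if not sites:
            zero_site_reps += 1
    return CalibrationResult(
        "branch_site_null_reject_rate", rejections / n_reps, n_reps,
        {"beb_zero_site_fraction": zero_site_reps / n_reps,
         "n_codons": n_codons, "alpha": alpha})


def beb_recovery(n_codons: int = 1000, omega2: float = 6.0,
                 p_selected: float = 0.10, seed: int = 0,
                 n_starts: int = 2) -> CalibrationResult:
    """Precision of BEB site detection under simulated positive selection
    on the foreground duplicate branch."""
    tree = TripletTree(0.2, 0.2, 0.5)
    classes = [(1 - p_selected, (0.1, 0.1, 0.1)),
               (p_selected, (omega2, 0.1, 0.1))]
    aln = simulate_codon_triplet(tree, 2.0, classes, n_codons=n_codons, seed=seed)
    fit = fit_branch_site(aln, "dup1", n_starts=n_starts)
    sites = beb_site_posteriors(fit, aln)
    true_sites = set(np.where(aln.site_classes == 1)[0] + 1)
    flagged = {s.position for s in sites}
    precision = (len(flagged & true_sites) / len(flagged)) if flagged else np.nan
    return CalibrationResult("beb_precision", precision, n_codons,
                             {"n_flagged": len(flagged), "omega2_hat": fit.omega2,
                              "lrt_p": fit.lrt.p_value})
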