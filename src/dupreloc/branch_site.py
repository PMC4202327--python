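"""Branch-site test of positive selection (Model A) with BEB site detection.

The accelerated duplicate is designated the foreground branch; the other
duplicate and the outgroup are background.  Model A mixes four site
classes::

    class 0   (prop p0)                 omega0 < 1 on every branch
    class 1   (prop p1)                 omega = 1 on every branch
    class 2a  (prop (1-p0-p1)*p0/(p0+p1))  background omega0, foreground omega2
    class 2b  (prop (1-p0-p1)*p1/(p0+p1))  background 1,      foreground omega2

The alternative lets omega2 >= 1 vary; the null fixes omega2 = 1 (one fewer
free parameter), and twice the log-likelihood difference is referred to
chi-square with df = 1.  Sites under positive selection are then located by
Bayes Empirical Bayes: the posterior probability that a site belongs to
class 2a/2b is averaged over a uniform prior grid on (p0, p1, omega0,
omega2) with branch lengths and kappa fixed at their MLEs; only sites with
posterior > 0.95 are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .codonmodels import CODON_AA, N_SENSE, codon_q, f3x4_freqs, syn_nonsyn_flux
from .dnds import gap_free_codon_columns
from .likelihood import LrtResult, lrt
from .simulate import TripletAlignment

BRANCH_BOUNDS = (1e-9, 50.0)
KAPPA_BOUNDS = (0.01, 100.0)
OMEGA2_MAX = 50.0
BEB_POSTERIOR_THRESHOLD = 0.95


@dataclass
class SelectedSite:
    """One positively selected site: 1-based alignment position, the
    foreground residue at that position, BEB posterior probability."""

    position: int
    residue: str
    posterior: float

    def __str__(self) -> str:  # Table-style "166E (1.000)"
        return f"{self.position}{self.residue} ({self.posterior:.3f})"


@dataclass
class BranchSiteResult:
    foreground: str
    p0: float
    p1: float
    p2_plus_p3: float
    omega0: float
    omega2: float
    lnl_alt: float
    lnl_null: float
    n_params_alt: int
    n_params_null: int
    null_omega2: float
    lrt: LrtResult = field(repr=False, default=None)
    branch_lengths: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kappa: float = 2.0
    selected_sites: list[SelectedSite] = field(default_factory=list)
    is_alternative: bool = True


def _class_props(p0: float, p1: float) -> np.ndarray:
    rest = 1.0 - p0 - p1
    denom = p0 + p1
    return np.array([p0, p1, rest * p0 / denom, rest * p1 / denom])


def _prepare(alignment: TripletAlignment, foreground: str):
    ids = list(alignment.ids)
    if foreground not in ids:
        raise ValueError(f"foreground {foreground!r} not among sequence ids {ids}")
    fg = ids.index(foreground)
    if fg == 2:
        raise ValueError("foreground must be one of the two duplicate branches")
    cols = gap_free_codon_columns(*alignment.seqs)
    key = (cols[0] * N_SENSE + cols[1]) * N_SENSE + cols[2]
    uniq, inverse, counts = np.unique(key, return_inverse=True, return_counts=True)
    xs = [uniq // (N_SENSE * N_SENSE), (uniq // N_SENSE) % N_SENSE, uniq % N_SENSE]
    return fg, xs, counts.astype(float), inverse, cols


def _branch_omegas(fg: int, omega0: float, omega2: float) -> np.ndarray:
    """(4 classes, 3 branches) omega layout of Model A."""
    out = np.empty((4, 3))
    for b in range(3):
        if b == fg:
            out[:, b] = (omega0, 1.0, omega2, omega2)
        else:
            out[:, b] = (omega0, 1.0, omega0, 1.0)
    return out


def _class_scales(fg: int, kappa: float, pi: tuple, props: np.ndarray,
                  omega0: float, omega2: float) -> np.ndarray:
    """Per-branch mean substitution rate over classes (the normalizer that
    makes branch lengths class-averaged substitutions per codon)."""
    a, b_flux = syn_nonsyn_flux(kappa, pi)
    mu = a + _branch_omegas(fg, omega0, omega2) * b_flux
    return props @ mu  # (3,)


def _class_site_likelihoods(xs, fg: int, lengths, kappa: float, pi: tuple,
                            omega0: float, omega2: float, props: np.ndarray,
                            fixed_scales: np.ndarray | None = None) -> np.ndarray:
    """(4, n_patterns) per-class site likelihoods.

    Site classes share one mutation process: class c on branch b runs at
    relative rate mu(omega_cb) / scale_b, where scale_b is the
    class-averaged rate (or a caller-fixed normalizer for BEB grids).
    """
    a, b_flux = syn_nonsyn_flux(kappa, pi)
    omegas = _branch_omegas(fg, omega0, omega2)
    mu = a + omegas * b_flux
    scales = (props @ mu) if fixed_scales is None else np.asarray(fixed_scales)
    pi_arr = np.asarray(pi)
    cache: dict[tuple[float, float], np.ndarray] = {}
    out = np.empty((4, xs[0].shape[0]))
    for c in range(4):
        prod = np.ones((N_SENSE, xs[0].shape[0]))
        for b in range(3):
            t_eff = float(lengths[b] * mu[c, b] / scales[b])
            key = (float(omegas[c, b]), t_eff)
            if key not in cache:
                cache[key] = codon_q(kappa, omegas[c, b], pi).transition_matrix(t_eff)
            prod *= cache[key][:, xs[b]]
        out[c] = pi_arr @ prod
    return out


def _mixture_lnl(class_l: np.ndarray, props: np.ndarray, counts: np.ndarray) -> float:
    site_l = props @ class_l
    if np.any(site_l <= 0):
        return -np.inf
    return float(np.log(site_l) @ counts)


def fit_branch_site(alignment: TripletAlignment, foreground: str,
                    freqs: np.ndarray | None = None, n_starts: int = 5,
                    ) -> BranchSiteResult:
    """Fit Model A alternative (omega2 free >= 1) and null (omega2 = 1).

    Free parameters: three branch lengths, kappa, the (p0, p1) simplex
    coordinates and omega0, plus omega2 in the alternative — 8 vs 7.
    Deterministic multi-start bounded L-BFGS-B.
    """
    fg, xs, counts, _, cols = _prepare(alignment, foreground)
    if freqs is None:
        freqs = f3x4_freqs(np.concatenate(cols))
    pi = tuple(np.asarray(freqs, float))

    # params: b1, b2, b3, kappa, v1 (=p0+p1), v2 (=p0/(p0+p1)), omega0[, omega2]
    eps = 1e-6
    bounds = [BRANCH_BOUNDS] * 3 + [KAPPA_BOUNDS] + [(eps, 1 - eps)] * 2 + [(eps, 1.0)]

    def unpack(v, omega2):
        lengths = tuple(v[:3])
        kappa = v[3]
        p0, p1 = v[4] * v[5], v[4] * (1 - v[5])
        w2 = v[7] if omega2 is None else omega2
        return lengths, kappa, p0, p1, v[6], w2

    def neg_lnl(v, omega2=None):
        lengths, kappa, p0, p1, w0, w2 = unpack(v, omega2)
        props = _class_props(p0, p1)
        class_l = _class_site_likelihoods(xs, fg, lengths, kappa, pi, w0, w2, props)
        return -_mixture_lnl(class_l, props, counts)

    starts = [
        [0.1, 0.1, 0.3, 2.0, 0.8, 0.7, 0.2, 3.0],
        [0.3, 0.3, 0.8, 2.0, 0.6, 0.5, 0.1, 1.5],
        [0.05, 0.05, 0.2, 4.0, 0.9, 0.8, 0.3, 8.0],
        [0.5, 0.5, 1.5, 1.0, 0.7, 0.6, 0.05, 2.0],
        [0.02, 0.02, 0.1, 2.0, 0.95, 0.5, 0.5, 1.1],
    ][:max(1, n_starts)]

    def run(omega2_fixed):
        nb = bounds + ([] if omega2_fixed is not None else [(1.0, OMEGA2_MAX)])
        best = None
        for s in starts:
            x0 = np.array(s[:len(nb)])
            res = optimize.minimize(neg_lnl, x0, args=(omega2_fixed,),
                                    method="L-BFGS-B", bounds=nb,
                                    options={"ftol": 1e-10, "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("branch-site optimization failed to converge")
        return best

    alt = run(None)
    null = run(1.0)
    lengths, kappa, p0, p1, w0, w2 = unpack(alt.x, None)
    lnl_alt, lnl_null = -float(alt.fun), -float(null.fun)
    result = lrt(lnl_alt, lnl_null, df=1)
    return BranchSiteResult(
        foreground=foreground, p0=p0, p1=p1, p2_plus_p3=1.0 - p0 - p1,
        omega0=w0, omega2=w2, lnl_alt=lnl_alt, lnl_null=lnl_null,
        n_params_alt=len(alt.x), n_params_null=len(null.x), null_omega2=1.0,
        lrt=result, branch_lengths=lengths, kappa=kappa, is_alternative=True)


def beb_site_posteriors(fit: BranchSiteResult, alignment: TripletAlignment,
                        grid_size: int = 10,
                        threshold: float = BEB_POSTERIOR_THRESHOLD,
                        ) -> list[SelectedSite]:
    """Bayes Empirical Bayes posteriors for class-2a/2b membership.

    A uniform prior grid is laid over (p0, p1) on the simplex (``grid_size``
    points per direction, pairs with p0 + p1 < 1), omega0 in (0, 1) and
    omega2 in [1, 11]; branch lengths and kappa stay at their MLEs.  The
    marginal posterior that each site belongs to the positively selected
    classes is averaged over the grid, and sites exceeding ``threshold``
    are returned with the foreground residue.
    """
    if not fit.is_alternative:
        raise ValueError("BEB requires the alternative-model fit")
    fg, xs, counts, inverse, cols = _prepare(alignment, fit.foreground)
    pi_arr = f3x4_freqs(np.concatenate(cols))
    pi = tuple(pi_arr)
    d = grid_size
    centers = (2 * np.arange(d) + 1) / (2 * d)
    w0_grid = centers                       # omega0 in (0, 1)
    w2_grid = 1.0 + 10.0 * centers          # omega2 in (1, 11)

    lengths, kappa = fit.branch_lengths, fit.kappa
    npat = counts.shape[0]
    # class rate normalizers fixed at the MLE so grid blocks stay separable
    props_mle = _class_props(max(fit.p0, 1e-6), max(fit.p1, 1e-6))
    scales = _class_scales(fg, kappa, pi, props_mle, fit.omega0, fit.omega2)

    def blocks(w0, w2):
        return _class_site_likelihoods(xs, fg, lengths, kappa, pi, w0, w2,
                                       props_mle, fixed_scales=scales)

    # class likelihood building blocks, indexed by grid omegas
    l0 = np.stack([blocks(w0, 1.0)[0] for w0 in w0_grid])    # (d, npat) class 0
    l1 = blocks(0.5, 1.0)[1]                                 # (npat,)
    l2a = np.empty((d, d, npat))
    l2b = np.empty((d, npat))
    for j, w2 in enumerate(w2_grid):
        block = blocks(0.5, w2)
        l2b[j] = block[3]
        for i, w0 in enumerate(w0_grid):
            l2a[i, j] = blocks(w0, w2)[2]

    # simplex grid on (p0, p1)
    pairs = [(a, b) for a in centers for b in centers if a + b < 1.0]
    post_num = np.zeros(npat)
    log_weights = []
    terms = []
    for p0, p1 in pairs:
        props = _class_props(p0, p1)
        # f: (d, d, npat) over (omega0, omega2)
        f = (props[0] * l0[:, None, :] + props[1] * l1[None, None, :]
             + props[2] * l2a + props[3] * l2b[None, :, :])
        f = np.clip(f, 1e-300, None)
        ll = np.tensordot(np.log(f), counts, axes=([2], [0]))  # (d, d)
        sel = props[2] * l2a + props[3] * l2b[None, :, :]
        log_weights.append(ll.ravel())
        terms.append((f.reshape(-1, npat), sel.reshape(-1, npat)))
    log_w = np.concatenate(log_weights)
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    off = 0
    for f_flat, sel_flat in terms:
        k = f_flat.shape[0]
        wt = w[off:off + k]
        post_num += wt @ (sel_flat / f_flat)
        off += k
    posterior_by_pattern = post_num  # (npat,)

    fg_codons = cols[fg]
    out = []
    site_posteriors = posterior_by_pattern[inverse]
    for pos0, (codon_idx, post) in enumerate(zip(fg_codons, site_posteriors)):
        if post > threshold:
            out.append(SelectedSite(position=pos0 + 1,
                                    residue=CODON_AA[int(codon_idx)],
                                    posterior=float(min(post, 1.0))))
    fit.selected_sites = out
    return out
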