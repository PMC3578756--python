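"""Single-marker and region-based association tests.

Single-marker scans use an additive logistic regression (likelihood-ratio
test, fitted on the aggregated 2x3 status-by-dosage table, which is a
sufficient statistic for the model).  Region tests — the
excess-of-significant-markers (ESM) statistic, the Madsen-Browning
general-genetic rank-sum and the Li-Leal multiple-marker Hotelling T^2 —
share one permutation procedure: case/control labels are permuted, the
statistic is recomputed for every permutation (including any
label-dependent ingredients such as Fisher p-values or control-frequency
weights), and the observed value is converted to a z-score against the
permutation distribution, with a two-tailed Gaussian p-value.

Significance conventions: 1e-8 for single-marker scans, 1e-6 for region
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.linalg import pinvh

from .panels import CaseControlPanel, MarkerFilter, filter_markers

__all__ = [
    "RegionTestResult",
    "ESMConfig",
    "logistic_single_marker",
    "logistic_scan",
    "fisher_exact_allele_test",
    "fisher_scan",
    "esm_statistic",
    "madsen_browning_ranksum",
    "li_leal_hotelling",
    "ESMTest",
    "MadsenBrowningTest",
    "LiLealTest",
    "permutation_test",
    "SINGLE_MARKER_ALPHA",
    "REGION_ALPHA",
]

SINGLE_MARKER_ALPHA = 1e-8
REGION_ALPHA = 1e-6


@dataclass(frozen=True)
class RegionTestResult:
    """Outcome of a permutation-calibrated region test."""

    statistic_name: str
    observed: float
    perm_mean: float
    perm_sd: float
    z: float
    p: float
    n_permutations: int


@dataclass(frozen=True)
class ESMConfig:
    """ESM settings: sum over the M most significant unique markers, with a
    minimum panel minor-allele count of 4 per marker."""

    M: int = 50
    min_minor_count: int = 4
    collapse_redundant: bool = True

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")


# ---------------------------------------------------------------------------
# single-marker logistic regression


def _status_dosage_tables(dosages: np.ndarray, case_mask: np.ndarray):
    """Aggregate (n, L) dosages into per-marker 2x3 tables."""
    case = case_mask.astype(bool)
    D = dosages
    n1d = np.stack([(D[case] == d).sum(axis=0) for d in (0, 1, 2)], axis=1)
    n0d = np.stack([(D[~case] == d).sum(axis=0) for d in (0, 1, 2)], axis=1)
    return n1d.astype(np.float64), n0d.astype(np.float64)


def _logistic_lrt_from_tables(n1d: np.ndarray, n0d: np.ndarray,
                              max_iter: int = 60, tol: float = 1e-10):
    """Vectorized Newton fit of logit P(case) = a + b*dosage per marker.

    Works on the aggregated tables; returns (deviance, p).  Quasi-separated
    markers converge in deviance even though |b| diverges, so iteration is
    capped and steps are clipped.
    """
    n1d = np.atleast_2d(n1d)
    n0d = np.atleast_2d(n0d)
    L = n1d.shape[0]
    d = np.array([0.0, 1.0, 2.0])
    tot = n1d + n0d
    n1 = n1d.sum(axis=1)
    n0 = n0d.sum(axis=1)
    n = n1 + n0

    a = np.log((n1 + 0.5) / (n0 + 0.5))
    b = np.zeros(L)
    for _ in range(max_iter):
        eta = a[:, None] + b[:, None] * d[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = tot * mu * (1.0 - mu)
        resid = n1d - tot * mu
        ga = resid.sum(axis=1)
        gb = (resid * d).sum(axis=1)
        waa = W.sum(axis=1) + 1e-12
        wab = (W * d).sum(axis=1)
        wbb = (W * d**2).sum(axis=1) + 1e-12
        det = waa * wbb - wab**2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        da = (wbb * ga - wab * gb) / det
        db = (waa * gb - wab * ga) / det
        np.clip(da, -5, 5, out=da)
        np.clip(db, -5, 5, out=db)
        a += da
        b += db
        if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < tol:
            break

    eta = a[:, None] + b[:, None] * d[None, :]
    # log-likelihoods, omitting the dosage-multinomial constant
    ll1 = (n1d * eta - tot * np.logaddexp(0.0, eta)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll0 = n1 * np.log(n1 / n) + n0 * np.log(n0 / n)
    ll0 = np.where(n1 * n0 == 0, 0.0, ll0)
    dev = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = sps.chi2.sf(dev, df=1)
    return dev, p


def logistic_scan(panel: CaseControlPanel, flt: MarkerFilter | None = None,
                  marker_idx: np.ndarray | None = None) -> np.ndarray:
    """Additive logistic-regression LRT p-value for each marker.

    Monomorphic-in-panel markers cannot occur (panels only keep segregating
    sites); markers excluded by the filter get NaN.
    """
    if marker_idx is None:
        marker_idx = (filter_markers(panel, flt) if flt is not None
                      else np.arange(panel.n_markers))
    p = np.full(panel.n_markers, np.nan)
    if marker_idx.size == 0:
        return p
    n1d, n0d = _status_dosage_tables(panel.dosages[:, marker_idx], panel.case_mask)
    _, pv = _logistic_lrt_from_tables(n1d, n0d)
    p[marker_idx] = pv
    return p


def logistic_single_marker(panel: CaseControlPanel, marker: int) -> float:
    """LRT p-value of the additive logistic regression at one marker."""
    dc = panel.dosages[:, [marker]]
    col = dc[:, 0]
    if col.min() == col.max():
        raise ValueError(f"marker {marker} is monomorphic in the panel")
    n1d, n0d = _status_dosage_tables(dc, panel.case_mask)
    _, pv = _logistic_lrt_from_tables(n1d, n0d)
    return float(pv[0])


# ---------------------------------------------------------------------------
# Fisher's exact allele-count test


def fisher_exact_allele_test(panel: CaseControlPanel, marker: int) -> float:
    """Two-sided Fisher's exact test on the 2x2 table of allele counts
    (derived/ancestral x case/control; the p-value is invariant to which
    allele is labelled minor)."""
    d = panel.dosages[:, marker].astype(np.int64)
    case = panel.case_mask
    k1 = int(d[case].sum())
    k0 = int(d[~case].sum())
    n1a = 2 * int(case.sum())
    n0a = 2 * int((~case).sum())
    table = [[k1, n1a - k1], [k0, n0a - k0]]
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def _fisher_lut(m: int, n_alleles: int, case_alleles: int) -> tuple[int, np.ndarray]:
    """Two-sided Fisher p for every possible count k of derived alleles in
    cases, at fixed margins (m derived among n_alleles; case_alleles drawn).

    Returns (kmin, p[k - kmin]).  Exact hypergeometric enumeration: the
    two-sided p at k sums pmf(k') over all k' with pmf(k') <= pmf(k).
    """
    kmin = max(0, m - (n_alleles - case_alleles))
    kmax = min(m, case_alleles)
    ks = np.arange(kmin, kmax + 1)
    pmf = sps.hypergeom.pmf(ks, n_alleles, m, case_alleles)
    # relative tolerance matches the convention of exact-test software
    thresh = pmf[:, None] * (1.0 + 1e-7)
    p = np.where(pmf[None, :] <= thresh, pmf[None, :], 0.0).sum(axis=1)
    return kmin, np.minimum(p, 1.0)


class _FisherLookup:
    """Per-panel cache of two-sided Fisher p-values indexed by (marker,
    derived-in-cases count); margins are fixed under label permutation."""

    def __init__(self, derived_totals: np.ndarray, n_alleles: int, case_alleles: int):
        self.n_alleles = n_alleles
        self.case_alleles = case_alleles
        luts = {}
        for m in np.unique(derived_totals):
            luts[int(m)] = _fisher_lut(int(m), n_alleles, case_alleles)
        offsets = np.zeros(derived_totals.size, dtype=np.int64)
        kmins = np.zeros(derived_totals.size, dtype=np.int64)
        flat = []
        pos = 0
        for j, m in enumerate(derived_totals):
            kmin, lut = luts[int(m)]
            offsets[j] = pos
            kmins[j] = kmin
            flat.append(lut)
            pos += lut.size
        self.offsets = offsets
        self.kmins = kmins
        self.flat = np.concatenate(flat) if flat else np.empty(0)

    def neglog10_p(self, k: np.ndarray) -> np.ndarray:
        """-log10 p for an array of derived-in-cases counts, shape
        (..., L) matching the marker axis last."""
        idx = self.offsets + (k - self.kmins)
        return -np.log10(self.flat[idx])


def fisher_scan(panel: CaseControlPanel, marker_idx: np.ndarray) -> np.ndarray:
    """Two-sided Fisher's exact allele-test p-values for a marker set."""
    D = panel.dosages[:, marker_idx].astype(np.int64)
    case = panel.case_mask
    m = D.sum(axis=0)
    k = D[case].sum(axis=0)
    lut = _FisherLookup(m, 2 * panel.n_individuals, 2 * int(case.sum()))
    return 10.0 ** (-lut.neglog10_p(k))


# ---------------------------------------------------------------------------
# region statistics


def esm_statistic(pvalues: np.ndarray, M: int, n_unique: int | None = None) -> float:
    """Excess-of-significant-markers statistic.

    With Y_1 >= Y_2 >= ... the sorted -log10 p-values of L unique markers,
    Z_M = sum_{i=1..min(M,L)} [ Y_i - (-log10 e_i) ], where e_i = i/(L+1)
    is the null expectation of the i-th smallest uniform order statistic.
    Larger when the region holds more marginally significant markers;
    monotone increasing as any included p-value shrinks.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    L = int(n_unique) if n_unique is not None else p.size
    m = min(int(M), p.size)
    Y = np.sort(-np.log10(p))[::-1][:m]
    i = np.arange(1, m + 1)
    expected = -np.log10(i / (L + 1))
    return float((Y - expected).sum())


def madsen_browning_ranksum(minor_dosages: np.ndarray, case_mask: np.ndarray) -> float:
    """Madsen-Browning rank-sum under the 'general genetic' model.

    Per-marker weight w_j = sqrt(n q_j (1-q_j)) with q_j estimated from
    controls with a pseudo-count: q_j = (minor copies in controls + 1) /
    (2 n_controls + 2).  Individual score = sum_j dosage_ij / w_j; the
    statistic is the sum of the ranks (midranks for ties) of case scores
    among all individuals.
    """
    D = np.asarray(minor_dosages, dtype=float)
    case = np.asarray(case_mask, dtype=bool)
    n = D.shape[0]
    n0 = int((~case).sum())
    mc = D[~case].sum(axis=0)
    q = (mc + 1.0) / (2.0 * n0 + 2.0)
    w = np.sqrt(n * q * (1.0 - q))
    scores = D @ (1.0 / w)
    ranks = sps.rankdata(scores, method="average")
    return float(ranks[case].sum())


def li_leal_hotelling(minor_dosages: np.ndarray, case_mask: np.ndarray) -> float:
    """Two-sample Hotelling T^2 on genotype scores (aa=-1, Aa=0, AA=1 for
    minor allele a), pooled covariance inverted by pseudoinverse.

    Returns NaN if the statistic is not finite (numerically degenerate
    covariance beyond the pseudoinverse tolerance).
    """
    X = np.asarray(minor_dosages, dtype=float) - 1.0
    case = np.asarray(case_mask, dtype=bool)
    n1 = int(case.sum())
    n0 = int((~case).sum())
    n = n1 + n0
    x1 = X[case].mean(axis=0)
    x0 = X[~case].mean(axis=0)
    S1 = np.cov(X[case], rowvar=False, ddof=1) if n1 > 1 else np.zeros((X.shape[1],) * 2)
    S0 = np.cov(X[~case], rowvar=False, ddof=1) if n0 > 1 else np.zeros((X.shape[1],) * 2)
    S = ((n1 - 1) * S1 + (n0 - 1) * S0) / (n - 2)
    S = np.atleast_2d(S)
    try:
        Sinv = pinvh(S)
    except np.linalg.LinAlgError:
        return float("nan")
    d = np.atleast_1d(x1 - x0)
    t2 = (n1 * n0 / n) * float(d @ Sinv @ d)
    return t2 if np.isfinite(t2) else float("nan")


# ---------------------------------------------------------------------------
# permutation framework


class ESMTest:
    """ESM region test: Fisher p-values are recomputed for every label
    permutation (the margins are fixed, so each permutation is a lookup of
    the derived-in-cases count)."""

    name = "esm"

    def __init__(self, panel: CaseControlPanel, flt: MarkerFilter,
                 config: ESMConfig | None = None):
        self.config = config or ESMConfig(M=50)
        use = MarkerFilter(study_type=flt.study_type, maf_min=flt.maf_min,
                           min_minor_count=self.config.min_minor_count)
        idx = filter_markers(panel, use, collapse_redundant=self.config.collapse_redundant)
        if idx.size == 0:
            raise ValueError("no unique markers pass the ESM filters")
        self.L = int(idx.size)
        D = panel.dosages[:, idx].astype(np.int64)
        self._D32 = D.astype(np.float32)
        self._lut = _FisherLookup(D.sum(axis=0), 2 * panel.n_individuals,
                                  2 * int(panel.case_mask.sum()))
        self._m = min(self.config.M, self.L)
        i = np.arange(1, self._m + 1)
        self._expected = -np.log10(i / (self.L + 1))

    def _zm_from_neglog(self, Y: np.ndarray) -> np.ndarray:
        m = self._m
        if Y.shape[-1] > m:
            part = np.partition(Y, Y.shape[-1] - m, axis=-1)[..., -m:]
        else:
            part = Y
        top = np.sort(part, axis=-1)[..., ::-1]
        return (top - self._expected).sum(axis=-1)

    def observed(self, case_mask: np.ndarray) -> float:
        k = self._D32[np.asarray(case_mask, bool)].sum(axis=0)
        Y = self._lut.neglog10_p(np.rint(k).astype(np.int64))
        return float(self._zm_from_neglog(Y[None, :])[0])

    def batch(self, case_matrix: np.ndarray) -> np.ndarray:
        C = case_matrix.astype(np.float32)
        K = np.rint(C @ self._D32).astype(np.int64)
        Y = self._lut.neglog10_p(K)
        return self._zm_from_neglog(Y)


class MadsenBrowningTest:
    """Madsen-Browning rank-sum test; control-frequency weights are
    recomputed for every permutation.  Redundant markers are not collapsed."""

    name = "madsen_browning"

    def __init__(self, panel: CaseControlPanel, flt: MarkerFilter):
        idx = filter_markers(panel, flt)
        if idx.size == 0:
            raise ValueError("no markers pass the study filter")
        self._D = panel.minor_dosages()[:, idx].astype(np.float64)
        self._n = panel.n_individuals

    def observed(self, case_mask: np.ndarray) -> float:
        return madsen_browning_ranksum(self._D, case_mask)

    def batch(self, case_matrix: np.ndarray) -> np.ndarray:
        C = case_matrix.astype(np.float64)
        n = self._n
        n0 = n - int(C[0].sum())
        colsum = self._D.sum(axis=0)
        mc = colsum[None, :] - C @ self._D
        q = (mc + 1.0) / (2.0 * n0 + 2.0)
        invw = 1.0 / np.sqrt(n * q * (1.0 - q))
        scores = self._D @ invw.T  # (n, P)
        ranks = sps.rankdata(scores, method="average", axis=0)
        return np.einsum("np,pn->p", ranks, C)


class LiLealTest:
    """Li-Leal multiple-marker Hotelling T^2 on the K rarest panel markers
    (by panel minor-allele frequency); redundant markers not collapsed."""

    name = "li_leal"

    def __init__(self, panel: CaseControlPanel, K: int = 50,
                 flt: MarkerFilter | None = None):
        maf = panel.markers["panel_maf"].to_numpy()
        idx = np.arange(panel.n_markers)
        if flt is not None:
            idx = filter_markers(panel, flt)
        order = idx[np.argsort(maf[idx], kind="stable")]
        self._idx = order[: min(K, order.size)]
        self._X = panel.minor_dosages()[:, self._idx].astype(np.float64) - 1.0
        self._XtX = self._X.T @ self._X
        self._colsum = self._X.sum(axis=0)

    def observed(self, case_mask: np.ndarray) -> float:
        case = np.asarray(case_mask, bool)
        return li_leal_hotelling(self._X + 1.0, case)

    def batch(self, case_matrix: np.ndarray) -> np.ndarray:
        C = case_matrix.astype(np.float64)
        n = self._X.shape[0]
        n1 = int(C[0].sum())
        n0 = n - n1
        M1 = (C @ self._X) / n1
        M0 = (self._colsum[None, :] - C @ self._X) / n0
        out = np.empty(C.shape[0])
        for p in range(C.shape[0]):
            m1, m0 = M1[p], M0[p]
            S = (self._XtX - n1 * np.outer(m1, m1) - n0 * np.outer(m0, m0)) / (n - 2)
            try:
                Sinv = pinvh(S)
            except np.linalg.LinAlgError:
                out[p] = np.nan
                continue
            d = m1 - m0
            out[p] = (n1 * n0 / n) * (d @ Sinv @ d)
        return out


def permutation_test(panel: CaseControlPanel, test, n_perm: int = 1000,
                     rng: np.random.Generator | None = None,
                     two_tailed: bool = True) -> RegionTestResult:
    """Permutation calibration of a region statistic.

    Case/control labels are permuted ``n_perm`` times; the observed
    statistic is converted to z = (observed - mean)/sd of the permutation
    distribution and to a Gaussian tail p-value (two-tailed by default).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    status = panel.status
    obs = test.observed(panel.case_mask)
    perm = rng.permuted(np.tile(status, (n_perm, 1)), axis=1)
    stats = np.asarray(test.batch(perm), dtype=float)
    good = np.isfinite(stats)
    mean = float(stats[good].mean()) if good.any() else float("nan")
    sd = float(stats[good].std(ddof=1)) if good.sum() > 1 else float("nan")
    if not np.isfinite(obs) or not np.isfinite(mean) or not np.isfinite(sd):
        z = p = float("nan")
    elif sd == 0:
        z = 0.0 if obs == mean else float(np.sign(obs - mean)) * float("inf")
        p = 1.0 if z == 0 else 0.0
    else:
        z = (obs - mean) / sd
        p = float(2.0 * sps.norm.sf(abs(z))) if two_tailed else float(sps.norm.sf(z))
        p = max(p, np.finfo(float).tiny)
    return RegionTestResult(
        statistic_name=getattr(test, "name", type(test).__name__),
        observed=float(obs), perm_mean=mean, perm_sd=sd,
        z=float(z), p=float(p), n_permutations=int(n_perm),
    )
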