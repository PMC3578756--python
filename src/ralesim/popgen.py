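"""Population-genetic summaries: site-frequency spectra, diversity, LD and
tagging analyses of simulated samples and panels.

Derived-allele polarity is known exactly from the simulator (mutations are
tracked from origin), so no outgroup or parsimony inference is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SFSSummary",
    "sfs",
    "diversity",
    "pi_from_sfs",
    "ld_r2",
    "tag_analysis",
    "singleton_burden_by_genotype",
]


@dataclass
class SFSSummary:
    """Unfolded site-frequency spectrum of a haplotype sample."""

    mutation_class: str      # "neutral" | "causative" | "all"
    n: int                   # haplotypes in the sample
    counts: np.ndarray       # counts[i] = number of sites at derived count i+1 (i = 0..n-2)

    @property
    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    @property
    def n_segregating(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (derived_count, n_sites, proportion), ready for TSV."""
        i = np.arange(1, self.n)
        return pd.DataFrame({"derived_count": i, "n_sites": self.counts,
                             "proportion": self.proportions})


def _class_mask(is_causative: np.ndarray, mutation_class: str) -> np.ndarray:
    if mutation_class == "all":
        return np.ones(is_causative.size, dtype=bool)
    if mutation_class == "neutral":
        return ~is_causative
    if mutation_class == "causative":
        return is_causative.copy()
    raise ValueError("mutation_class must be 'neutral', 'causative' or 'all'")


def sfs(haplotypes: np.ndarray, is_causative: np.ndarray,
        mutation_class: str = "all") -> SFSSummary:
    """Unfolded SFS of the requested mutation class in a haplotype sample.

    ``haplotypes`` is a (n, L) 0/1 matrix; a site contributes to bin i if
    exactly i haplotypes carry the derived allele (0 < i < n).
    """
    n = haplotypes.shape[0]
    mask = _class_mask(np.asarray(is_causative, dtype=bool), mutation_class)
    dc = haplotypes[:, mask].sum(axis=0, dtype=np.int64)
    dc = dc[(dc > 0) & (dc < n)]
    counts = np.bincount(dc, minlength=n)[1:n]
    return SFSSummary(mutation_class=mutation_class, n=n, counts=counts)


def diversity(haplotypes: np.ndarray, is_causative: np.ndarray | None = None,
              mutation_class: str = "all") -> dict:
    """Segregating sites S and mean pairwise difference count pi.

    pi is the average number of differing sites between two distinct
    haplotypes, computed from per-site derived counts:
    pi = sum_j 2 c_j (n - c_j) / (n (n-1)).
    """
    n = haplotypes.shape[0]
    if is_causative is None:
        is_causative = np.zeros(haplotypes.shape[1], dtype=bool)
    mask = _class_mask(np.asarray(is_causative, dtype=bool), mutation_class)
    c = haplotypes[:, mask].sum(axis=0, dtype=np.int64)
    c = c[(c > 0) & (c < n)]
    S = int(c.size)
    pi = float((2.0 * c * (n - c)).sum() / (n * (n - 1)))
    return {"S": S, "pi": pi}


def pi_from_sfs(summary: SFSSummary) -> float:
    """pi recovered from the SFS identity pi = sum_i i (n-i) xi_i * 2/(n(n-1))."""
    n = summary.n
    i = np.arange(1, n)
    return float((2.0 * i * (n - i) * summary.counts).sum() / (n * (n - 1)))


def ld_r2(haplotypes: np.ndarray, a: int, b: int) -> float:
    """Squared correlation of allele indicators at two sites on phased
    haplotypes.  Symmetric in its arguments and invariant to allele-label
    swaps; undefined (ValueError) for monomorphic sites."""
    x = haplotypes[:, a].astype(float)
    y = haplotypes[:, b].astype(float)
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        raise ValueError("r^2 undefined for a monomorphic site")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov**2 / (vx * vy))


def _r2_matrix(H: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """r^2 between each site in idx_a and each in idx_b (vectorized)."""
    X = H[:, idx_a].astype(float)
    Y = H[:, idx_b].astype(float)
    X -= X.mean(axis=0)
    Y -= Y.mean(axis=0)
    n = H.shape[0]
    cov = X.T @ Y / n
    sx = (X**2).mean(axis=0)
    sy = (Y**2).mean(axis=0)
    denom = np.outer(sx, sy)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, cov**2 / denom, np.nan)


def tag_analysis(panel, significant_markers: np.ndarray) -> pd.DataFrame:
    """LD between significant common neutral markers and causative sites.

    For each marker index in ``significant_markers``, ranks all causative
    markers in the panel by r^2 (computed on phased haplotypes) and records
    the top two, together with the identity, panel frequency and effect of
    the best-tagged causative site.  Returns one row per significant marker;
    the number of unique tagged causative sites is
    ``df['top_causative'].nunique()``.
    """
    caus_idx = np.flatnonzero(panel.markers["is_causative"].to_numpy())
    rows = []
    if caus_idx.size == 0 or len(significant_markers) == 0:
        return pd.DataFrame(
            columns=["marker", "top_causative", "top_r2", "second_r2",
                     "tagged_freq", "tagged_effect"]
        )
    r2 = _r2_matrix(panel.haplotypes, np.asarray(significant_markers), caus_idx)
    freq = panel.markers["derived_count"].to_numpy() / (2 * panel.n_individuals)
    eff = panel.markers["effect"].to_numpy()
    for i, m in enumerate(np.asarray(significant_markers)):
        vals = r2[i]
        order = np.argsort(vals)[::-1]
        top = caus_idx[order[0]]
        rows.append(
            {
                "marker": int(m),
                "top_causative": int(top),
                "top_r2": float(vals[order[0]]),
                "second_r2": float(vals[order[1]]) if caus_idx.size > 1 else np.nan,
                "tagged_freq": float(freq[top]),
                "tagged_effect": float(eff[top]),
            }
        )
    return pd.DataFrame(rows)


def singleton_burden_by_genotype(panel, focal_marker: int,
                                 matched_marker: int | None = None) -> pd.DataFrame:
    """Mean causative-singleton count per genotype class at a marker.

    For the focal marker (and optionally a frequency-matched null marker),
    individuals are grouped by derived-allele dosage {0, 1, 2} and the mean
    +- SE number of causative panel singletons they carry is reported.
    """
    dc = panel.markers["derived_count"].to_numpy()
    singleton_caus = np.flatnonzero((dc == 1) & panel.markers["is_causative"].to_numpy())
    burden = panel.dosages[:, singleton_caus].sum(axis=1) if singleton_caus.size else \
        np.zeros(panel.n_individuals, dtype=np.int64)
    rows = []
    targets = [("focal", focal_marker)]
    if matched_marker is not None:
        targets.append(("matched", matched_marker))
    for label, m in targets:
        d = panel.dosages[:, m]
        for g in (0, 1, 2):
            sel = d == g
            k = int(sel.sum())
            mean = float(burden[sel].mean()) if k else np.nan
            se = float(burden[sel].std(ddof=1) / np.sqrt(k)) if k > 1 else np.nan
            rows.append({"marker_role": label, "genotype": g, "n": k,
                         "mean_singletons": mean, "se": se})
    return pd.DataFrame(rows)


def match_null_marker(panel, focal_marker: int, pvalues: np.ndarray,
                      p_threshold: float = 1e-4) -> int | None:
    """Frequency-matched non-associated marker for the singleton-burden
    comparison: nearest panel derived count (within +-1 copy preferred,
    else nearest) among markers with single-marker p > ``p_threshold``,
    ties broken by position order."""
    dc = panel.markers["derived_count"].to_numpy()
    ok = np.flatnonzero((pvalues > p_threshold) & (np.arange(dc.size) != focal_marker))
    if ok.size == 0:
        return None
    diff = np.abs(dc[ok] - dc[focal_marker])
    best = ok[diff == diff.min()]
    return int(best[0])
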