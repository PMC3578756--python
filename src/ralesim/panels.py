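"""Case/control panel construction, marker filtering and chip ascertainment.

Cases are drawn from the upper 15% of the realized liability distribution of
the whole population; controls from within one standard deviation of the
population mean.  Panels retain phased haplotypes (the simulator knows true
phase), a dosage matrix of derived-allele copies, and per-marker metadata,
restricted to sites segregating within the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simcore import Population
from . import phenotype as phen

__all__ = [
    "CaseControlPanel",
    "MarkerFilter",
    "draw_case_control",
    "filter_markers",
    "ascertain_chip",
    "population_sample",
]


@dataclass(frozen=True)
class MarkerFilter:
    """Marker inclusion rules for a study design.

    ``gwas`` keeps markers with panel minor-allele frequency >= ``maf_min``
    (default 5%, emulating a chip that types every common SNP);
    ``resequencing`` keeps all markers.  ``min_minor_count`` additionally
    requires a minimum panel minor-allele count (region-based tests use 4).
    """

    study_type: str = "resequencing"  # "gwas" | "resequencing"
    maf_min: float = 0.05
    min_minor_count: int = 0

    def __post_init__(self):
        if self.study_type not in ("gwas", "resequencing"):
            raise ValueError("study_type must be 'gwas' or 'resequencing'")
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")


GWAS = MarkerFilter(study_type="gwas")
RESEQ = MarkerFilter(study_type="resequencing")


class CaseControlPanel:
    """A case/control genotype panel.

    Attributes
    ----------
    haplotypes : (2n, L) uint8
        Phased panel haplotypes (two consecutive rows per individual;
        cases first).
    dosages : (n, L) uint8
        Derived-allele copy counts per individual.
    status : (n,) uint8
        1 = case, 0 = control.
    markers : DataFrame
        position, effect, is_causative, origin_generation, derived_count
        (panel), panel_maf, control_maf (general-population minor allele),
        minor_is_derived.
    """

    def __init__(self, haplotypes, status, markers, phenotypes=None):
        self.haplotypes = haplotypes
        self.status = np.asarray(status, dtype=np.uint8)
        self.dosages = haplotypes[0::2].astype(np.uint8) + haplotypes[1::2].astype(np.uint8)
        self.markers = markers
        self.phenotypes = phenotypes

    @property
    def n_individuals(self) -> int:
        return self.status.size

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return self.status.astype(bool)

    def minor_dosages(self) -> np.ndarray:
        """Dosage matrix recoded to panel minor-allele copies."""
        flip = ~self.markers["minor_is_derived"].to_numpy()
        D = self.dosages.astype(np.int16)
        D[:, flip] = 2 - D[:, flip]
        return D

    def subset_markers(self, idx) -> "CaseControlPanel":
        idx = np.asarray(idx)
        return CaseControlPanel(
            self.haplotypes[:, idx],
            self.status.copy(),
            self.markers.iloc[idx].reset_index(drop=True),
            phenotypes=self.phenotypes,
        )


def draw_case_control(pop: Population, n_cases: int, n_controls: int,
                      rng: np.random.Generator,
                      case_quantile: float = 0.85,
                      control_sd_window: float = 1.0) -> CaseControlPanel:
    """Sample a case/control panel from the population's realized liabilities.

    Cases are sampled uniformly without replacement from individuals at or
    above the ``case_quantile`` (default upper 15%) of the population
    liability distribution; controls from individuals within
    ``control_sd_window`` population SDs of the population mean.  Raises
    ``ValueError`` naming the deficient stratum if too few individuals
    qualify.
    """
    ph = phen.population_phenotypes(pop, rng)
    P = ph["P"].to_numpy()
    thr = np.quantile(P, case_quantile)
    mean, sd = P.mean(), P.std(ddof=1)
    case_pool = np.flatnonzero(P >= thr)
    # controls: within the SD window AND below the case threshold (with pure
    # environmental noise the 85th percentile ~ 1.036 SD sits so close to the
    # window edge that sampling noise can otherwise make the strata overlap)
    control_pool = np.flatnonzero((np.abs(P - mean) <= control_sd_window * sd) & (P < thr))
    if case_pool.size < n_cases:
        raise ValueError(
            f"only {case_pool.size} individuals qualify as cases "
            f"(liability >= {100 * (1 - case_quantile):.0f}% upper tail), need {n_cases}"
        )
    if control_pool.size < n_controls:
        raise ValueError(
            f"only {control_pool.size} individuals qualify as controls "
            f"(within {control_sd_window} SD of the mean), need {n_controls}"
        )
    cases = rng.choice(case_pool, size=n_cases, replace=False)
    controls = rng.choice(control_pool, size=n_controls, replace=False)
    overlap = np.intersect1d(cases, controls)
    if overlap.size:
        # cannot happen at the default thresholds (the upper 15% lies more
        # than 1 SD above the mean); assert the strata are disjoint
        raise ValueError("case and control strata overlap; narrow the thresholds")

    individuals = np.concatenate([cases, controls])
    hap_rows = np.empty(2 * individuals.size, dtype=np.int64)
    hap_rows[0::2] = 2 * individuals
    hap_rows[1::2] = 2 * individuals + 1
    H = pop.haplotypes[hap_rows]

    # population (general) minor allele per marker, from the whole population
    two_n_pop = pop.n_haplotypes
    pop_freq = pop.counts / two_n_pop
    minor_is_derived = pop_freq <= 0.5

    panel_count = H.sum(axis=0, dtype=np.int64)
    seg = (panel_count > 0) & (panel_count < H.shape[0])
    H = H[:, seg]
    panel_count = panel_count[seg]
    two_n = H.shape[0]
    panel_freq = panel_count / two_n
    panel_maf = np.minimum(panel_freq, 1 - panel_freq)

    ctrl_rows = H[2 * n_cases:]
    ctrl_count = ctrl_rows.sum(axis=0, dtype=np.int64)
    ctrl_freq_derived = ctrl_count / ctrl_rows.shape[0]
    mid = minor_is_derived[seg]
    control_maf = np.where(mid, ctrl_freq_derived, 1 - ctrl_freq_derived)

    markers = pd.DataFrame(
        {
            "position": pop.positions[seg],
            "effect": pop.effects[seg],
            "is_causative": pop.is_causative[seg],
            "origin_generation": pop.origins[seg],
            "derived_count": panel_count,
            "panel_maf": panel_maf,
            "control_maf": control_maf,
            "minor_is_derived": mid,
        }
    )
    status = np.concatenate([np.ones(n_cases, np.uint8), np.zeros(n_controls, np.uint8)])
    pheno = ph.iloc[individuals].reset_index(drop=True)
    return CaseControlPanel(H, status, markers, phenotypes=pheno)


def filter_markers(panel: CaseControlPanel, flt: MarkerFilter,
                   collapse_redundant: bool = False) -> np.ndarray:
    """Indices of panel markers passing a study filter.

    GWAS keeps panel-MAF >= maf_min; resequencing keeps all.  A positive
    ``min_minor_count`` drops markers whose panel minor-allele count is
    below it.  With ``collapse_redundant``, markers with identical dosage
    columns are collapsed to a single representative (the first by position
    order).
    """
    maf = panel.markers["panel_maf"].to_numpy()
    two_n = 2 * panel.n_individuals
    minor_count = np.rint(np.minimum(maf, 1 - maf) * two_n).astype(np.int64)
    keep = np.ones(panel.n_markers, dtype=bool)
    if flt.study_type == "gwas":
        keep &= maf >= flt.maf_min
    if flt.min_minor_count > 0:
        keep &= minor_count >= flt.min_minor_count
    idx = np.flatnonzero(keep)
    if collapse_redundant and idx.size:
        D = panel.dosages[:, idx]
        _, first = np.unique(D, axis=1, return_index=True)
        idx = idx[np.sort(first)]
    return idx


def ascertain_chip(panel: CaseControlPanel, rng: np.random.Generator,
                   maf_min: float = 0.05) -> np.ndarray:
    """Sample an 'imperfect' genotyping chip from the panel's markers.

    Candidate markers have control-population MAF >= ``maf_min`` (minor
    allele defined in the general population); marker j is included iff a
    uniform draw on (0,1] is <= its expected control heterozygosity
    2 q_j (1 - q_j).  Applied to a neutral marker pool this yields an
    approximately uniform MAF distribution on [maf_min, 0.5].
    """
    q = panel.markers["control_maf"].to_numpy()
    candidates = q >= maf_min
    u = rng.uniform(0.0, 1.0, size=q.size)
    kept = candidates & (u <= 2.0 * q * (1.0 - q))
    return np.flatnonzero(kept)


def population_sample(pop: Population, n_diploids: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Phased haplotypes (2n rows) of ``n_diploids`` individuals drawn
    without replacement from the population."""
    if n_diploids > pop.N:
        raise ValueError(f"cannot sample {n_diploids} diploids from N={pop.N}")
    ind = rng.choice(pop.N, size=n_diploids, replace=False)
    rows = np.empty(2 * n_diploids, dtype=np.int64)
    rows[0::2] = 2 * ind
    rows[1::2] = 2 * ind + 1
    return pop.haplotypes[rows]
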