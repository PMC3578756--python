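"""Forward-time Wright-Fisher simulation of a recombining gene region.

Individuals are diploid; the population is a matrix of 2N haplotypes over
the currently segregating mutation columns (infinitely-many-sites: every
mutation occupies a unique position on the continuous interval [0, 1)).
Each generation, N offspring are formed by sampling two parents per
offspring with probability proportional to fitness (with replacement,
selfing permitted); each parent transmits one gamete built by Poisson(r)
uniform crossovers and Poisson(mu) new mutations.

Neutral columns never influence the dynamics, so extinct/fixed-column
cleanup and full count recomputation are amortized over a window of
generations; causative columns are tracked every generation because they
determine fitness.  Snapshots returned to the caller are always fully
compacted, with columns sorted by position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import SimParams
from . import phenotype as phen

__all__ = [
    "Mutation",
    "Population",
    "initialize_population",
    "make_gamete",
    "next_generation",
    "evolve",
]

_CLEANUP_INTERVAL = 16


@dataclass(frozen=True)
class Mutation:
    """A single segregating mutation."""

    position: float
    effect: float
    is_causative: bool
    origin_generation: int
    count: int


class Population:
    """A compacted snapshot of the population at one generation.

    Attributes
    ----------
    haplotypes : (2N, L) uint8 array
        Presence/absence of each segregating mutation on each haplotype,
        columns sorted by position.
    positions, effects, is_causative, origins, counts : (L,) arrays
        Per-mutation metadata; counts are derived-allele copy numbers among
        the 2N haplotypes.
    fixed_burden : float
        Summed effect of causative mutations fixed during the run (added as
        a constant to every haplotype effect sum).
    optimum : float
        Current stabilizing-selection optimum (equals fixed_burden when
        optimum recentering is enabled, else 0).
    """

    def __init__(self, params: SimParams, generation: int, haplotypes: np.ndarray,
                 positions: np.ndarray, effects: np.ndarray, is_causative: np.ndarray,
                 origins: np.ndarray, counts: np.ndarray,
                 fixed_burden: float = 0.0, optimum: float = 0.0,
                 fixations: list | None = None):
        self.params = params
        self.generation = int(generation)
        self.haplotypes = haplotypes
        self.positions = positions
        self.effects = effects
        self.is_causative = is_causative
        self.origins = origins
        self.counts = counts
        self.fixed_burden = float(fixed_burden)
        self.optimum = float(optimum)
        self.fixations = fixations if fixations is not None else []

    # -- basic accessors ----------------------------------------------------

    @property
    def N(self) -> int:
        return self.params.N

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_mutations(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def sigma_e(self) -> float:
        return self.params.sigma_e

    @property
    def sigma_s(self) -> float:
        return self.params.sigma_s

    def mutation(self, j: int) -> Mutation:
        return Mutation(
            position=float(self.positions[j]),
            effect=float(self.effects[j]),
            is_causative=bool(self.is_causative[j]),
            origin_generation=int(self.origins[j]),
            count=int(self.counts[j]),
        )

    def mutation_table(self) -> pd.DataFrame:
        """Mutation metadata as a DataFrame (one row per segregating site)."""
        return pd.DataFrame(
            {
                "position": self.positions,
                "effect": self.effects,
                "is_causative": self.is_causative,
                "origin_generation": self.origins,
                "count": self.counts,
            }
        )

    def haplotype_mutations(self, i: int) -> np.ndarray:
        """Column indices of the mutations carried by haplotype ``i``
        (columns are position-sorted, so this is sorted by position)."""
        return np.flatnonzero(self.haplotypes[i])

    def haplotype_effect_sums(self) -> np.ndarray:
        """Per-haplotype additive causative effect sums, including the
        fixed burden."""
        ci = np.flatnonzero(self.is_causative & (self.effects > 0))
        if ci.size == 0:
            E = np.zeros(self.n_haplotypes)
        else:
            E = self.haplotypes[:, ci].astype(float) @ self.effects[ci]
        return E + self.fixed_burden

    def recompute_counts(self) -> np.ndarray:
        """Recount derived-allele copies from the haplotype matrix (the
        stored ``counts`` must always equal this)."""
        return self.haplotypes.sum(axis=0, dtype=np.int64)


# ---------------------------------------------------------------------------
# Operations


def initialize_population(params: SimParams) -> Population:
    """Mutation-free population of 2N haplotypes at generation 0."""
    L = 0
    return Population(
        params=params,
        generation=0,
        haplotypes=np.zeros((2 * params.N, L), dtype=np.uint8),
        positions=np.empty(L),
        effects=np.empty(L),
        is_causative=np.zeros(L, dtype=bool),
        origins=np.empty(L, dtype=np.int64),
        counts=np.empty(L, dtype=np.int64),
    )


def make_gamete(hap_a: np.ndarray, hap_b: np.ndarray, positions: np.ndarray,
                params: SimParams, rng: np.random.Generator):
    """Form one gamete from a diploid parent.

    Crossovers: Poisson(r) breakpoints uniform on [0,1); the gamete
    alternates between the two parental haplotypes at each breakpoint,
    starting from a uniformly chosen one.  New mutations: Poisson(mu_total)
    fresh positions, each causative with probability mu_d/mu_total (effect
    Exponential(lambda)), else neutral (effect 0).

    Returns ``(carrier, new_mutations)`` where ``carrier`` is the 0/1 vector
    over the existing mutation columns and ``new_mutations`` is a list of
    ``(position, effect, is_causative)`` tuples.
    """
    hap_a = np.asarray(hap_a, dtype=np.uint8)
    hap_b = np.asarray(hap_b, dtype=np.uint8)
    start = int(rng.integers(0, 2))
    first, second = (hap_a, hap_b) if start == 0 else (hap_b, hap_a)
    n_x = rng.poisson(params.r)
    if n_x == 0:
        carrier = first.copy()
    else:
        breaks = np.sort(rng.uniform(0.0, 1.0, size=n_x))
        parity = np.searchsorted(breaks, positions, side="right") % 2
        carrier = np.where(parity == 0, first, second).astype(np.uint8)
    new_mutations = []
    mu_tot = params.mu_total
    n_new = rng.poisson(mu_tot) if mu_tot > 0 else 0
    for _ in range(n_new):
        pos = float(rng.uniform(0.0, 1.0))
        is_c = bool(rng.random() < params.mu_causative / mu_tot)
        eff = float(rng.exponential(params.lambda_effect)) if is_c else 0.0
        new_mutations.append((pos, eff if is_c else 0.0, is_c))
    return carrier, new_mutations


class _Engine:
    """Internal stepping engine.

    Haplotypes are stored copy-on-write: the population is a vector of
    references (``ref``) into a pool of distinct haplotype rows, and a
    gamete that experiences neither crossover nor mutation simply reuses its
    parental row.  Per-generation work therefore scales with the number of
    recombination/mutation events rather than with 2N x L.  Extinct rows
    and extinct/fixed mutation columns are garbage-collected every
    ``_CLEANUP_INTERVAL`` generations; neutral columns never influence the
    dynamics, so the lag is invisible, and the <=16-generation lag in
    recognising a causative fixation only delays the (rare) optimum
    recentering bookkeeping.
    """

    def __init__(self, pop: Population):
        self.params = pop.params
        self.N = pop.params.N
        self.generation = pop.generation
        two_n = 2 * self.N
        L = pop.n_mutations
        self.L = L
        self._row_cap = two_n + 4096
        self._col_cap = max(2 * L, 256)
        self.pool = np.zeros((self._row_cap, self._col_cap), dtype=np.uint8)
        self.pool[:two_n, :L] = pop.haplotypes
        self.R = two_n  # pool rows in use
        self.ref = np.arange(two_n, dtype=np.int64)
        self.positions = pop.positions.copy()
        self.effects = pop.effects.copy()
        self.is_causative = pop.is_causative.copy()
        self.origins = pop.origins.copy()
        self.fixed_burden = pop.fixed_burden
        self.optimum = pop.optimum
        self.fixations = list(pop.fixations)
        # per-pool-row causative effect sum (excluding the fixed burden)
        self.E_pool = np.zeros(self._row_cap)
        self.E_pool[:two_n] = pop.haplotype_effect_sums() - pop.fixed_burden
        self._since_cleanup = 0

    # -- capacity -----------------------------------------------------------

    def _ensure_capacity(self, rows: int, cols: int) -> None:
        if rows <= self._row_cap and cols <= self._col_cap:
            return
        new_rows = max(rows + 4096, self._row_cap)
        new_cols = max(cols + 512, self._col_cap) if cols > self._col_cap else self._col_cap
        grown = np.zeros((new_rows, new_cols), dtype=np.uint8)
        grown[: self.R, : self.L] = self.pool[: self.R, : self.L]
        self.pool = grown
        if new_rows > self._row_cap:
            E = np.zeros(new_rows)
            E[: self.R] = self.E_pool[: self.R]
            self.E_pool = E
        self._row_cap, self._col_cap = new_rows, new_cols

    # -- fitness ------------------------------------------------------------

    def _fitness(self, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        E = self.E_pool[self.ref] + self.fixed_burden
        G = np.sqrt(E[0::2] * E[1::2])
        P = G if p.sigma_e == 0 else G + rng.normal(0.0, p.sigma_e, size=self.N)
        w = phen.fitness(P, p.sigma_s, optimum=self.optimum)
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise RuntimeError("all-zero or invalid fitness vector")
        return w / total

    # -- one generation -----------------------------------------------------

    def step(self, rng: np.random.Generator) -> None:
        p = self.params
        two_n = 2 * self.N
        L = self.L

        probs = self._fitness(rng)
        # inverse-CDF sampling of parents proportional to fitness
        cdf = np.cumsum(probs)
        parents = np.minimum(np.searchsorted(cdf, rng.random(two_n), side="right"),
                             self.N - 1)
        start = rng.integers(0, 2, size=two_n)
        src = 2 * parents + start          # transmitted strand, gamete-wise
        pr = self.ref[src]                 # its pool row
        other_pr = self.ref[src ^ 1]       # the parent's other strand

        n_x = rng.poisson(p.r, size=two_n) if p.r > 0 else np.zeros(two_n, dtype=np.int64)
        if p.mu_total > 0:
            n_mut = rng.poisson(p.mu_total, size=two_n)
        else:
            n_mut = np.zeros(two_n, dtype=np.int64)
        tot_new = int(n_mut.sum())

        modified = np.flatnonzero((n_x > 0) | (n_mut > 0))
        m = modified.size
        self._ensure_capacity(self.R + m, L + tot_new)
        pool = self.pool

        new_ref = pr
        if m:
            rows = self.R + np.arange(m)
            new_ref = pr.copy()
            new_ref[modified] = rows
            # start from the transmitted strand
            pool[self.R : self.R + m, :L] = pool[pr[modified], :L]

            # crossovers
            recomb_local = np.flatnonzero(n_x[modified] > 0)
            if recomb_local.size and L:
                self._apply_crossovers(pool, rows, modified, recomb_local,
                                       other_pr, n_x, rng)
            elif p.r > 0:
                k_all = n_x[modified][recomb_local] if recomb_local.size else n_x[n_x > 0]
                tot_b = int(k_all.sum())
                if tot_b:
                    rng.uniform(0.0, 1.0, size=tot_b)  # keep stream aligned

            # new mutations
            if tot_new:
                while True:
                    new_pos = rng.uniform(0.0, 1.0, size=tot_new)
                    if np.unique(new_pos).size == tot_new:
                        break
                is_c = rng.random(tot_new) < (p.mu_causative / p.mu_total)
                new_eff = np.where(is_c & (p.lambda_effect > 0),
                                   rng.exponential(p.lambda_effect or 1.0, size=tot_new), 0.0)
                # map each new mutation to the pool row of its gamete
                gam_of_new = np.repeat(modified, n_mut[modified])
                row_of_new = new_ref[gam_of_new]
                pool[self.R : self.R + m, L : L + tot_new] = 0
                pool[row_of_new, L + np.arange(tot_new)] = 1

                self.positions = np.concatenate([self.positions[:L], new_pos])
                self.effects = np.concatenate([self.effects[:L], new_eff])
                self.is_causative = np.concatenate([self.is_causative[:L], is_c])
                self.origins = np.concatenate(
                    [self.origins[:L], np.full(tot_new, self.generation + 1, dtype=np.int64)]
                )
                self.L = L + tot_new

            # effect sums for the new rows (only effect-bearing columns
            # contribute; control runs with all-zero effects skip this)
            ci = np.flatnonzero(self.effects[: self.L])
            if ci.size:
                block = pool[self.R : self.R + m, : self.L][:, ci]
                self.E_pool[self.R : self.R + m] = (
                    block.astype(np.float64) @ self.effects[ci]
                )
            else:
                self.E_pool[self.R : self.R + m] = 0.0
            self.R += m

        self.ref = new_ref
        self.generation += 1
        self._since_cleanup += 1
        if self._since_cleanup >= _CLEANUP_INTERVAL:
            self.cleanup()

    def _apply_crossovers(self, pool, rows, modified, recomb_local,
                          other_pr, n_x, rng: np.random.Generator) -> None:
        """Apply crossovers to the freshly copied rows.  Entries whose
        position falls in an odd-parity segment (counting Poisson-uniform
        breakpoints from the left) switch to the other parental strand."""
        L = self.L
        pos = self.positions[:L]
        gam = modified[recomb_local]
        k = n_x[gam]
        breaks = rng.uniform(0.0, 1.0, size=int(k.sum()))
        offsets = np.concatenate([[0], np.cumsum(k)[:-1]])
        rws = rows[recomb_local]
        oth = other_pr[gam]

        single = k == 1
        if single.any():
            b = breaks[offsets[single]]
            mask = pos[None, :] >= b[:, None]
            rsel = rws[single]
            now = pool[rsel, :L]
            np.copyto(now, pool[oth[single], :L], where=mask)
            pool[rsel, :L] = now
        for i in np.flatnonzero(k > 1):
            bk = np.sort(breaks[offsets[i]: offsets[i] + k[i]])
            parity = np.searchsorted(bk, pos, side="right") % 2
            r_i = rws[i]
            pool[r_i, :L] = np.where(parity == 0, pool[r_i, :L], pool[oth[i], :L])

    # -- garbage collection -------------------------------------------------

    def cleanup(self) -> None:
        """Compact the pool to live rows and the columns to segregating
        mutations; fold fixed causative effects into the fixed burden."""
        two_n = 2 * self.N
        L = self.L
        live, inv = np.unique(self.ref, return_inverse=True)
        nl = live.size
        refcount = np.bincount(inv, minlength=nl).astype(np.float32)
        rows = self.pool[live, :L]  # materialized live x L block
        if L:
            counts = np.rint(refcount @ rows.astype(np.float32)).astype(np.int64)
            fixed = counts == two_n
            fixed_causative = fixed & self.is_causative[:L]
            if fixed_causative.any():
                gained = float(self.effects[:L][fixed_causative].sum())
                self.fixed_burden += gained
                for j in np.flatnonzero(fixed_causative):
                    self.fixations.append(
                        (float(self.positions[j]), float(self.effects[j]),
                         int(self.origins[j]), int(self.generation))
                    )
                if self.params.recenter_optimum:
                    self.optimum = self.fixed_burden
                # every live row carried the fixed columns; their effect now
                # lives in fixed_burden instead of E_pool
                self.E_pool[live] -= gained
            keep = np.flatnonzero((counts > 0) & ~fixed)
            if keep.size != L:
                rows = np.take(rows, keep, axis=1)
                self.positions = self.positions[keep]
                self.effects = self.effects[keep]
                self.is_causative = self.is_causative[keep]
                self.origins = self.origins[keep]
        Lk = rows.shape[1]
        E_live = self.E_pool[live].copy()
        self.pool[: self.R, : max(L, Lk)] = 0
        self.pool[:nl, :Lk] = rows
        self.E_pool[:nl] = E_live
        self.ref = inv.astype(np.int64)
        self.R = nl
        self.L = Lk
        self._since_cleanup = 0

    def snapshot(self) -> Population:
        self.cleanup()
        L = self.L
        if L and np.unique(self.positions[:L]).size != L:
            raise RuntimeError("position collision violated infinite-sites model")
        order = np.argsort(self.positions[:L], kind="stable")
        H = np.ascontiguousarray(self.pool[self.ref][:, order])
        counts = H.sum(axis=0, dtype=np.int64)
        return Population(
            params=self.params,
            generation=self.generation,
            haplotypes=H,
            positions=self.positions[:L][order].copy(),
            effects=self.effects[:L][order].copy(),
            is_causative=self.is_causative[:L][order].copy(),
            origins=self.origins[:L][order].copy(),
            counts=counts,
            fixed_burden=self.fixed_burden,
            optimum=self.optimum,
            fixations=list(self.fixations),
        )


def next_generation(pop: Population, params: SimParams | None = None,
                    rng: np.random.Generator | None = None) -> Population:
    """Advance the population one generation (fitness-proportional parent
    sampling with replacement; mutation and recombination per gamete)."""
    params = params or pop.params
    if rng is None:
        rng = np.random.default_rng(params.seed)
    eng = _Engine(Population(
        params=params, generation=pop.generation, haplotypes=pop.haplotypes,
        positions=pop.positions, effects=pop.effects, is_causative=pop.is_causative,
        origins=pop.origins, counts=pop.counts, fixed_burden=pop.fixed_burden,
        optimum=pop.optimum, fixations=pop.fixations,
    ))
    eng.step(rng)
    return eng.snapshot()


def evolve(params: SimParams, rng: np.random.Generator | None = None,
           n_generations: int | None = None) -> Population:
    """Evolve from a mutation-free population for ``params.n_generations``
    generations (deterministic given the seed)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_gen = params.n_generations if n_generations is None else n_generations
    eng = _Engine(initialize_population(params))
    for _ in range(n_gen):
        eng.step(rng)
    return eng.snapshot()
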