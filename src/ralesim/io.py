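"""Serialization: HDF5 populations, TSV tables, VCF panel export/import.

Populations are stored as an HDF5 container holding the mutation table and
the haplotypes as ragged index arrays (CSR-style flat indices + offsets).
Panels export to VCF (via pysam) with integer base-pair coordinates mapped
from the unit interval onto a 100 kb region, phased genotypes, and effect
annotations in INFO; case/control status travels in a sidecar sample sheet.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import pysam

from .params import SimParams
from .simcore import Population
from .panels import CaseControlPanel

__all__ = [
    "save_population",
    "load_population",
    "write_mutation_tsv",
    "write_panel_vcf",
    "read_panel_vcf",
    "write_dosage_tsv",
]

REGION_BP = 100_000

_PARAM_FIELDS = ("N", "mu_neutral", "mu_causative", "r", "lambda_effect",
                 "sigma_e", "sigma_s", "n_generations", "seed", "recenter_optimum")


def save_population(pop: Population, path) -> None:
    """Write a population snapshot to HDF5."""
    H = pop.haplotypes
    flat = [np.flatnonzero(H[i]).astype(np.int64) for i in range(H.shape[0])]
    offsets = np.zeros(H.shape[0] + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([f.size for f in flat])
    indices = np.concatenate(flat) if flat else np.empty(0, dtype=np.int64)
    with h5py.File(path, "w") as f:
        f.attrs["generation"] = pop.generation
        f.attrs["fixed_burden"] = pop.fixed_burden
        f.attrs["optimum"] = pop.optimum
        for k in _PARAM_FIELDS:
            f.attrs[f"param_{k}"] = getattr(pop.params, k)
        g = f.create_group("mutations")
        g.create_dataset("position", data=pop.positions)
        g.create_dataset("effect", data=pop.effects)
        g.create_dataset("is_causative", data=pop.is_causative.astype(np.uint8))
        g.create_dataset("origin_generation", data=pop.origins)
        g.create_dataset("count", data=pop.counts)
        h = f.create_group("haplotypes")
        h.create_dataset("indices", data=indices, compression="gzip")
        h.create_dataset("offsets", data=offsets)
        if pop.fixations:
            f.create_dataset("fixations", data=np.array(pop.fixations, dtype=float))


def load_population(path) -> Population:
    with h5py.File(path, "r") as f:
        kw = {k: f.attrs[f"param_{k}"] for k in _PARAM_FIELDS}
        kw["N"] = int(kw["N"])
        kw["n_generations"] = int(kw["n_generations"])
        kw["seed"] = int(kw["seed"])
        kw["recenter_optimum"] = bool(kw["recenter_optimum"])
        params = SimParams(**kw)
        positions = f["mutations/position"][:]
        L = positions.size
        indices = f["haplotypes/indices"][:]
        offsets = f["haplotypes/offsets"][:]
        n_hap = offsets.size - 1
        H = np.zeros((n_hap, L), dtype=np.uint8)
        for i in range(n_hap):
            H[i, indices[offsets[i]: offsets[i + 1]]] = 1
        fixations = [tuple(row) for row in f["fixations"][:]] if "fixations" in f else []
        return Population(
            params=params,
            generation=int(f.attrs["generation"]),
            haplotypes=H,
            positions=positions,
            effects=f["mutations/effect"][:],
            is_causative=f["mutations/is_causative"][:].astype(bool),
            origins=f["mutations/origin_generation"][:],
            counts=f["mutations/count"][:],
            fixed_burden=float(f.attrs["fixed_burden"]),
            optimum=float(f.attrs["optimum"]),
            fixations=fixations,
        )


def write_mutation_tsv(pop: Population, path) -> None:
    """Plain-TSV mutation table (position, effect, class, origin, count)."""
    pop.mutation_table().to_csv(path, sep="\t", index=False)


def _bp_positions(positions: np.ndarray) -> np.ndarray:
    """Map unit-interval positions to unique 1-based integer bp: floor(pos *
    REGION_BP) + 1, resolving collisions by shifting +1 in position order."""
    bp = np.floor(positions * REGION_BP).astype(np.int64) + 1
    order = np.argsort(positions, kind="stable")
    out = bp.copy()
    last = 0
    for j in order:
        out[j] = max(bp[j], last + 1)
        last = out[j]
    return out


def write_panel_vcf(panel: CaseControlPanel, vcf_path, sample_sheet_path=None) -> None:
    """Export a panel as an uncompressed VCF with phased genotypes.

    INFO fields: EFFECT (liability effect size), CAUSATIVE (flag), ORIGIN
    (origin generation), DCOUNT (panel derived count).  The REF/ALT alleles
    are synthetic (A = ancestral, T = derived).  Status goes to a sidecar
    sample-sheet TSV.
    """
    n = panel.n_individuals
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID=region,length={REGION_BP}>")
    header.add_line('##INFO=<ID=EFFECT,Number=1,Type=Float,Description="Liability effect size">')
    header.add_line('##INFO=<ID=CAUSATIVE,Number=0,Type=Flag,Description="Causative-class mutation">')
    header.add_line('##INFO=<ID=ORIGIN,Number=1,Type=Integer,Description="Origin generation">')
    header.add_line('##INFO=<ID=DCOUNT,Number=1,Type=Integer,Description="Panel derived allele count">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = [f"I{i:05d}" for i in range(n)]
    for s in samples:
        header.add_sample(s)
    pos_bp = _bp_positions(panel.markers["position"].to_numpy())
    order = np.argsort(pos_bp)
    H = panel.haplotypes
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vf:
        for j in order:
            rec = vf.new_record(
                contig="region", start=int(pos_bp[j]) - 1,
                stop=int(pos_bp[j]), alleles=("A", "T"),
            )
            rec.id = f"m{j}"
            rec.info["EFFECT"] = float(panel.markers["effect"].iloc[j])
            if bool(panel.markers["is_causative"].iloc[j]):
                rec.info["CAUSATIVE"] = True
            rec.info["ORIGIN"] = int(panel.markers["origin_generation"].iloc[j])
            rec.info["DCOUNT"] = int(panel.markers["derived_count"].iloc[j])
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = (int(H[2 * i, j]), int(H[2 * i + 1, j]))
                rec.samples[s].phased = True
            vf.write(rec)
    if sample_sheet_path is None:
        sample_sheet_path = str(vcf_path) + ".samples.tsv"
    pd.DataFrame({"sample": samples, "status": np.where(panel.status == 1, "case", "control")}) \
        .to_csv(sample_sheet_path, sep="\t", index=False)


def read_panel_vcf(vcf_path, sample_sheet_path=None) -> CaseControlPanel:
    """Rebuild a panel from a VCF + sample sheet (phased GT required)."""
    if sample_sheet_path is None:
        sample_sheet_path = str(vcf_path) + ".samples.tsv"
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    status = (sheet["status"] == "case").to_numpy().astype(np.uint8)
    recs = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        gts = []
        for rec in vf:
            recs.append(rec)
            g = np.array([rec.samples[s]["GT"] for s in samples], dtype=np.int16)
            gts.append(g.reshape(-1))
    if not recs:
        raise ValueError("empty VCF")
    G = np.stack(gts, axis=1).astype(np.uint8)  # (2n, L) haplotypes
    # order samples as sheet order (VCF sample order == sheet order on export)
    n = len(samples)
    markers = pd.DataFrame({
        "position": [(r.pos - 0.5) / REGION_BP for r in recs],
        "effect": [float(r.info.get("EFFECT", 0.0)) for r in recs],
        "is_causative": [bool(r.info.get("CAUSATIVE", False)) for r in recs],
        "origin_generation": [int(r.info.get("ORIGIN", -1)) for r in recs],
    })
    dcount = G.sum(axis=0).astype(np.int64)
    freq = dcount / (2 * n)
    markers["derived_count"] = dcount
    markers["panel_maf"] = np.minimum(freq, 1 - freq)
    ctrl = np.repeat(status == 0, 2)
    cf = G[ctrl].sum(axis=0) / max(int(ctrl.sum()), 1)
    minor_is_derived = freq <= 0.5
    markers["control_maf"] = np.where(minor_is_derived, cf, 1 - cf)
    markers["minor_is_derived"] = minor_is_derived
    return CaseControlPanel(G, status, markers)


def write_dosage_tsv(panel: CaseControlPanel, path) -> None:
    """Native TSV dosage matrix: one row per individual (status first
    column), one column per marker keyed by bp position."""
    pos_bp = _bp_positions(panel.markers["position"].to_numpy())
    df = pd.DataFrame(panel.dosages, columns=[f"bp{b}" for b in pos_bp])
    df.insert(0, "status", np.where(panel.status == 1, "case", "control"))
    df.to_csv(path, sep="\t", index=False)
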