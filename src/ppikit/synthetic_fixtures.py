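"""Deterministic synthetic fixtures for every pipeline stage.

Each generator takes a frozen spec with a mandatory seed and produces
inputs in the exact dialects the reader modules consume: idealized
two-chain structures with controllable contact geometry plus matching score
JSONs, benchmark score tables with separable class distributions, residue
tables with a planted logit mutation model, and planted-partition edge
lists with evidence columns.

Toy complexes use an idealized geometry (two parallel strands with
adjustable separation); only whether distances fall within or beyond the
8 A contact cutoff matters to any downstream computation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ppikit.calibration import CONTROL_SETS, POSITIVE_SETS

__all__ = [
    "ToyComplexSpec",
    "ToyComplexResult",
    "make_toy_complex",
    "BenchmarkSpec",
    "make_benchmark_table",
    "MutationSpec",
    "make_mutation_dataset",
    "GraphSpec",
    "make_planted_graph",
]

_RES_SPACING = 12.0  # along-strand spacing keeps non-planted pairs > 12 A apart


# ---------------------------------------------------------------------------
# Toy complexes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyComplexSpec:
    """Geometry and PAE parameters of one synthetic dimer."""

    seed: int
    len_a: int = 10
    len_b: int = 8
    n_contacts: int = 4
    interface_pae: float = 6.0
    background_pae: float = 30.0
    interface_pae_ba: float | None = None  # optional directional asymmetry
    contact_distance: float = 5.0
    noncontact_distance: float = 30.0
    plddt: float = 80.0
    glycine_positions: tuple = ()  # (chain_index, residue_index) pairs

    def __post_init__(self) -> None:
        if self.len_a < 3 or self.len_b < 3:
            raise ValueError("chain lengths must be >= 3")
        if self.n_contacts > min(self.len_a, self.len_b):
            raise ValueError(
                f"{self.n_contacts} planted contacts infeasible for chains "
                f"{self.len_a}/{self.len_b}"
            )
        if not 0 < self.contact_distance < 8:
            raise ValueError("contact_distance must lie in (0, 8)")
        if self.noncontact_distance <= 12:
            raise ValueError("noncontact_distance must exceed 12")


@dataclass
class ToyComplexResult:
    pdb_path: Path
    json_path: Path
    expected_lis: float
    expected_clis: float
    expected_ilis: float
    n_contacts: int


def _expected_block_mean(
    n_iface: int, iface: float, n_bg: int, bg: float, cutoff: float = 12.0
) -> float:
    total, count = 0.0, 0
    if n_iface and iface <= cutoff:
        total += n_iface * (cutoff - iface) / cutoff
        count += n_iface
    if n_bg and bg <= cutoff:
        total += n_bg * (cutoff - bg) / cutoff
        count += n_bg
    return total / count if count else 0.0


def expected_toy_scores(spec: ToyComplexSpec) -> tuple[float, float, float]:
    """Closed-form expected (lis, clis, ilis) for a toy-complex spec."""
    k = spec.n_contacts
    iface_ab = spec.interface_pae
    iface_ba = spec.interface_pae_ba if spec.interface_pae_ba is not None else iface_ab
    n_bg = spec.len_a * spec.len_b - k
    lis_ab = _expected_block_mean(k, iface_ab, n_bg, spec.background_pae)
    lis_ba = _expected_block_mean(k, iface_ba, n_bg, spec.background_pae)
    lis = (lis_ab + lis_ba) / 2.0
    clis_ab = _expected_block_mean(k, iface_ab, 0, spec.background_pae)
    clis_ba = _expected_block_mean(k, iface_ba, 0, spec.background_pae)
    clis = (clis_ab + clis_ba) / 2.0
    return lis, clis, math.sqrt(lis * clis)


def _write_toy_pdb(spec: ToyComplexSpec, path: Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    gly = set(spec.glycine_positions)
    atoms = []
    for chain_idx, (chain_id, length) in enumerate((("A", spec.len_a), ("B", spec.len_b))):
        for i in range(length):
            x = _RES_SPACING * i
            if chain_idx == 0:
                y = 0.0
            else:
                y = spec.contact_distance if i < spec.n_contacts else spec.noncontact_distance
            rep = np.array([x, y, 0.0])
            is_gly = (chain_idx, i) in gly
            res_name = "GLY" if is_gly else "ALA"
            common = dict(chain_id=chain_id, res_id=i + 1, res_name=res_name,
                          element="C", b_factor=spec.plddt)
            # representative point: CB normally, CA for glycine
            atoms.append(struc.Atom(rep + [0.0, 0.0, 1.5], atom_name="N", **{**common, "element": "N"}))
            if is_gly:
                atoms.append(struc.Atom(rep, atom_name="CA", **common))
            else:
                atoms.append(struc.Atom(rep + [0.0, 0.0, 1.5], atom_name="CA", **common))
                atoms.append(struc.Atom(rep, atom_name="CB", **common))
    f = PDBFile()
    f.set_structure(struc.array(atoms))
    f.write(str(path))


def make_toy_complex(
    spec: ToyComplexSpec, out_dir, pair_id: str = "toy", rank: int = 1
) -> ToyComplexResult:
    """Write a synthetic dimer PDB and score JSON; return expected scores.

    Planted contact pairs are (i, i) for i < ``n_contacts``, at
    ``contact_distance``; every other inter-chain pair is farther than 12 A.
    Inter-chain PAE equals ``interface_pae`` on planted pairs (optionally a
    different value in the B->A direction) and ``background_pae`` elsewhere;
    intra-chain PAE is 1.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_path = out_dir / f"{pair_id}_rank_{rank:03d}.pdb"
    json_path = out_dir / f"{pair_id}_scores_rank_{rank:03d}.json"
    _write_toy_pdb(spec, pdb_path)

    la, lb = spec.len_a, spec.len_b
    n = la + lb
    iface_ba = spec.interface_pae_ba if spec.interface_pae_ba is not None else spec.interface_pae
    pae = np.ones((n, n))
    pae[:la, la:] = spec.background_pae
    pae[la:, :la] = spec.background_pae
    for i in range(spec.n_contacts):
        pae[i, la + i] = spec.interface_pae
        pae[la + i, i] = iface_ba
    payload = {
        "pae": pae.tolist(),
        "plddt": [spec.plddt] * n,
        "ptm": 0.8,
        "iptm": 0.7,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh)
    lis, clis, ilis = expected_toy_scores(spec)
    return ToyComplexResult(pdb_path, json_path, lis, clis, ilis, spec.n_contacts)


# ---------------------------------------------------------------------------
# Benchmark score tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkSpec:
    """Separable positive/control score distributions per metric."""

    seed: int
    n_pos: int = 200
    n_ctrl: int = 600
    metrics: tuple = ("ilis", "iptm")
    pos_beta: tuple = (5.0, 2.0)
    ctrl_beta: tuple = (2.0, 5.0)


def make_benchmark_table(spec: BenchmarkSpec) -> pd.DataFrame:
    """Seeded benchmark table with positive and control score rows."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_pos):
        rows.append(
            {
                "pair_id": f"pos{i:05d}",
                "set_label": POSITIVE_SETS[i % len(POSITIVE_SETS)],
                "class": "positive",
            }
        )
    for i in range(spec.n_ctrl):
        rows.append(
            {
                "pair_id": f"ctl{i:05d}",
                "set_label": CONTROL_SETS[i % len(CONTROL_SETS)],
                "class": "control",
            }
        )
    df = pd.DataFrame(rows)
    df["plddt_subgroup"] = rng.choice(["0-50", "50-70", "70-100"], size=len(df))
    is_pos = (df["class"] == "positive").to_numpy()
    for metric in spec.metrics:
        for choice in ("best", "avg"):
            v = np.where(
                is_pos,
                rng.beta(*spec.pos_beta, size=len(df)),
                rng.beta(*spec.ctrl_beta, size=len(df)),
            )
            df[f"{metric}_{choice}"] = v
    return df


# ---------------------------------------------------------------------------
# Mutation datasets with a planted logit model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationSpec:
    """Planted mutation model logit(p) = b0 + b1*clir_pct + b2*phylop."""

    seed: int
    n_genes: int = 50
    n_residues: int = 200  # per gene
    beta0: float = -6.0
    beta1: float = 0.03
    beta2: float = 0.0
    p_zero_lir: float = 0.4
    p_zero_clir: float = 0.3  # P(clir = 0 | lir > 0)
    phylop_mean: float = 2.0
    phylop_sd: float = 1.0
    phylop_clir_rho: float = 0.0


def make_mutation_dataset(spec: MutationSpec):
    """Residue table + mutation records drawn from the planted model.

    Returns ``(table, records, truth)`` where ``truth`` holds the planted
    coefficients for recovery tests. ``clir_pct <= lir_pct`` holds by
    construction and the mutation indicator is Bernoulli with
    ``logit(p) = beta0 + beta1 * clir_pct + beta2 * phylop``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes * spec.n_residues
    gene = np.repeat([f"g{i:04d}" for i in range(spec.n_genes)], spec.n_residues)
    position = np.tile(np.arange(1, spec.n_residues + 1), spec.n_genes)
    aa = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n)

    lir = np.where(rng.random(n) < spec.p_zero_lir, 0.0, rng.uniform(0.0, 100.0, n))
    clir = lir * rng.uniform(0.0, 1.0, n)
    clir[rng.random(n) < spec.p_zero_clir] = 0.0
    clir = np.minimum(clir, lir)

    noise = rng.normal(0.0, 1.0, n)
    if spec.phylop_clir_rho:
        z = (clir - clir.mean()) / (clir.std() or 1.0)
        raw = spec.phylop_clir_rho * z + math.sqrt(1 - spec.phylop_clir_rho**2) * noise
    else:
        raw = noise
    phylop = spec.phylop_mean + spec.phylop_sd * raw

    logit = spec.beta0 + spec.beta1 * clir + spec.beta2 * phylop
    p = 1.0 / (1.0 + np.exp(-logit))
    mutated = rng.random(n) < p

    table = pd.DataFrame(
        {
            "gene": gene,
            "position": position,
            "aa": aa,
            "lir_pct": lir,
            "clir_pct": clir,
            "phylop": phylop,
            "mutated": mutated,
        }
    )
    from ppikit.allele_enrichment import MutationRecord

    letters = "ACDEFGHIKLMNPQRSTVWY"
    records = []
    for _, r in table[table["mutated"]].iterrows():
        alt = letters[(letters.index(r["aa"]) + 1) % len(letters)]
        records.append(
            MutationRecord(gene=r["gene"], position=int(r["position"]), ref_aa=r["aa"],
                           alt_aa=alt, source="synthetic")
        )
    truth = {"beta0": spec.beta0, "beta1": spec.beta1, "beta2": spec.beta2}
    return table, records, truth


# ---------------------------------------------------------------------------
# Planted-partition graphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GraphSpec:
    """Stochastic block model, optionally with a two-level hierarchy.

    ``n_super`` super-blocks each contain ``n_sub`` sub-blocks of
    ``sub_size`` nodes; edge probabilities are ``p_in`` within a sub-block,
    ``p_mid`` between sub-blocks of the same super-block, ``p_out`` across
    super-blocks. ``decoy_rate`` adds extra edges that fail the downstream
    confidence/evidence filter.
    """

    seed: int
    n_super: int = 2
    n_sub: int = 3
    sub_size: int = 30
    p_in: float = 0.3
    p_mid: float = 0.04
    p_out: float = 0.005
    decoy_rate: float = 0.01
    ilis_threshold: float = 0.223

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_mid, self.p_out, self.decoy_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def make_planted_graph(spec: GraphSpec):
    """Edge list with evidence columns plus planted labels.

    Returns ``(edges, labels)``: ``edges`` has columns gene_a, gene_b,
    ilis_best, literature_support, ortholog_score (planted edges always
    pass the default filter, decoys never do); ``labels`` maps each node to
    its super- and sub-block.
    """
    rng = np.random.default_rng(spec.seed)
    n_nodes = spec.n_super * spec.n_sub * spec.sub_size
    names = [f"n{i:04d}" for i in range(n_nodes)]
    super_lab = np.repeat(np.arange(spec.n_super), spec.n_sub * spec.sub_size)
    sub_lab = np.repeat(np.arange(spec.n_super * spec.n_sub), spec.sub_size)

    rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if sub_lab[i] == sub_lab[j]:
                p = spec.p_in
            elif super_lab[i] == super_lab[j]:
                p = spec.p_mid
            else:
                p = spec.p_out
            u = rng.random()
            if u < p:
                lit = rng.random() < 0.5
                rows.append(
                    {
                        "gene_a": names[i],
                        "gene_b": names[j],
                        "ilis_best": rng.uniform(spec.ilis_threshold + 0.05, 0.95),
                        "literature_support": lit,
                        "ortholog_score": int(rng.integers(4, 16)) if not lit
                        else int(rng.integers(0, 16)),
                    }
                )
            elif u < p + spec.decoy_rate:
                # decoy: low score, or good score with no supporting evidence
                if rng.random() < 0.5:
                    rows.append(
                        {
                            "gene_a": names[i],
                            "gene_b": names[j],
                            "ilis_best": rng.uniform(0.0, spec.ilis_threshold - 0.02),
                            "literature_support": bool(rng.random() < 0.5),
                            "ortholog_score": int(rng.integers(0, 16)),
                        }
                    )
                else:
                    rows.append(
                        {
                            "gene_a": names[i],
                            "gene_b": names[j],
                            "ilis_best": rng.uniform(spec.ilis_threshold, 0.95),
                            "literature_support": False,
                            "ortholog_score": int(rng.integers(0, 4)),
                        }
                    )
    edges = pd.DataFrame(rows)
    labels = pd.DataFrame(
        {"node": names, "super_block": super_lab, "sub_block": sub_lab}
    )
    return edges, labels
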