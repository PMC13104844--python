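"""Readers for predicted-complex artifacts and contact-geometry derivation.

Coordinates are reduced to one representative point per residue: the C-beta
atom, falling back to C-alpha when C-beta is absent (always for glycine).
Per-residue pLDDT is taken from the B-factor column of the coordinate file.
PAE matrices are stored exactly as read; any symmetrization happens
downstream, explicitly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ComplexModel",
    "ScoreBundle",
    "PredictionSet",
    "FormatError",
    "StructureError",
    "read_structure",
    "read_scores",
    "contact_map",
    "discover_models",
]


class FormatError(ValueError):
    """Raised when an input file does not parse as the declared format."""


class StructureError(ValueError):
    """Raised when a parsed structure violates the dimer contract."""


@dataclass
class ComplexModel:
    """A parsed two-chain predicted structure.

    Attributes
    ----------
    pair_id : str
        Identifier of the protein pair.
    rank : int
        Model rank (1..5), 1 being the top-ranked model.
    chains : list of (chain_id, sequence)
        One-letter amino-acid sequence per chain, in file order.
    residue_coords : (n, 3) ndarray
        Representative (C-beta proxy) coordinate per residue, in Angstrom,
        concatenated over chains in order.
    plddt : (n,) ndarray
        Per-residue pLDDT in [0, 100].
    chain_offsets : tuple of int
        Start index of each chain in the concatenated residue order.
    """

    pair_id: str
    rank: int
    chains: list[tuple[str, str]]
    residue_coords: np.ndarray
    plddt: np.ndarray
    chain_offsets: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        self.residue_coords = np.asarray(self.residue_coords, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        if not self.chain_offsets:
            offsets, pos = [], 0
            for _, seq in self.chains:
                offsets.append(pos)
                pos += len(seq)
            self.chain_offsets = tuple(offsets)
        n = sum(len(seq) for _, seq in self.chains)
        if self.residue_coords.shape != (n, 3):
            raise StructureError(
                f"expected {n} residue coordinates, got {self.residue_coords.shape}"
            )
        if self.plddt.shape != (n,):
            raise StructureError(f"expected {n} pLDDT values, got {self.plddt.shape}")
        if np.any((self.plddt < 0) | (self.plddt > 100)):
            raise StructureError("pLDDT values must lie in [0, 100]")

    @property
    def n_residues(self) -> int:
        return self.residue_coords.shape[0]

    @property
    def chain_lengths(self) -> tuple[int, ...]:
        return tuple(len(seq) for _, seq in self.chains)

    def chain_slice(self, chain_index: int) -> slice:
        """Slice of the concatenated residue order covering one chain."""
        start = self.chain_offsets[chain_index]
        return slice(start, start + self.chain_lengths[chain_index])


@dataclass
class ScoreBundle:
    """PAE matrix plus global confidences for one predicted model.

    The PAE matrix is stored unmodified; entry (i, j) is the expected error
    of residue j's position when the prediction is aligned on residue i.
    """

    pair_id: str
    rank: int
    pae: np.ndarray
    ptm: float
    iptm: float
    plddt: np.ndarray

    def __post_init__(self) -> None:
        self.pae = np.asarray(self.pae, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
            raise FormatError(f"PAE matrix must be square, got {self.pae.shape}")
        if np.any(self.pae < 0):
            raise FormatError("PAE entries must be non-negative")
        for name, v in (("ptm", self.ptm), ("iptm", self.iptm)):
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"{name} must lie in [0, 1], got {v}")

    @property
    def n_residues(self) -> int:
        return self.pae.shape[0]


@dataclass
class PredictionSet:
    """All ranked models for one protein pair, ordered by rank."""

    pair_id: str
    models: list[tuple[ComplexModel, ScoreBundle]]

    def __post_init__(self) -> None:
        ranks = [m.rank for m, _ in self.models]
        if len(set(ranks)) != len(ranks) or ranks != sorted(ranks):
            raise ValueError(f"model ranks must be unique and ascending, got {ranks}")
        if self.models:
            ref = [seq for _, seq in self.models[0][0].chains]
            for model, bundle in self.models:
                if [seq for _, seq in model.chains] != ref:
                    raise ValueError("all models of a pair must share sequences")
                if bundle.n_residues != model.n_residues:
                    raise ValueError(
                        f"rank {model.rank}: PAE size {bundle.n_residues} does not "
                        f"match residue count {model.n_residues}"
                    )


def _residue_records(atoms):
    """Group an atom array into residues, preserving chain and file order."""
    from biotite.sequence import ProteinSequence

    records = []  # (chain_id, res_id, one_letter, cb_or_ca_coord, plddt)
    # stable grouping on (chain_id, res_id) transitions
    keys = list(zip(atoms.chain_id, atoms.res_id))
    start = 0
    for i in range(1, len(keys) + 1):
        if i == len(keys) or keys[i] != keys[start]:
            sub = atoms[start:i]
            chain_id = sub.chain_id[0]
            res_name = str(sub.res_name[0])
            try:
                one = ProteinSequence.convert_letter_3to1(res_name)
            except Exception as exc:
                raise StructureError(
                    f"non-standard residue {res_name} at {chain_id}:{sub.res_id[0]}"
                ) from exc
            names = list(sub.atom_name)
            if "CB" in names:
                idx = names.index("CB")
            elif "CA" in names:
                idx = names.index("CA")
            else:
                raise StructureError(
                    f"residue {chain_id}:{sub.res_id[0]} ({res_name}) has neither CB nor CA"
                )
            records.append(
                (str(chain_id), int(sub.res_id[0]), one, sub.coord[idx], float(sub.b_factor[idx]))
            )
            start = i
    return records


def read_structure(path, format: str | None = None, pair_id: str = "", rank: int = 1) -> ComplexModel:
    """Read a two-chain predicted structure from a PDB or mmCIF file.

    Parameters
    ----------
    path : path-like
        Coordinate file with pLDDT in the B-factor column.
    format : {"pdb", "mmcif", None}
        File format; inferred from the suffix when None.
    pair_id, rank
        Metadata attached to the returned model.

    Returns
    -------
    ComplexModel
        With C-beta proxy coordinates (C-alpha when C-beta is absent).

    Raises
    ------
    FormatError
        If the file cannot be parsed as the named format.
    StructureError
        If a residue lacks both CB and CA, or the file has more than 2 chains.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"?": "pdb", ".pdb": "pdb", ".cif": "mmcif", ".mmcif": "mmcif"}.get(suffix)
        if format is None:
            raise FormatError(f"cannot infer format from suffix {suffix!r}")
    try:
        if format == "pdb":
            from biotite.structure.io.pdb import PDBFile

            atoms = PDBFile.read(str(path)).get_structure(model=1, extra_fields=["b_factor"])
        elif format == "mmcif":
            from biotite.structure.io.pdbx import CIFFile, get_structure

            atoms = get_structure(CIFFile.read(str(path)), model=1, extra_fields=["b_factor"])
        else:
            raise FormatError(f"unknown format {format!r}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not parse {path} as {format}: {exc}") from exc

    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise StructureError(f"{path}: no polymer atoms")
    records = _residue_records(atoms)

    chains: list[tuple[str, str]] = []
    coords, plddt = [], []
    for chain_id, _res_id, one, coord, b in records:
        if not chains or chains[-1][0] != chain_id:
            chains.append((chain_id, ""))
        chains[-1] = (chain_id, chains[-1][1] + one)
        coords.append(coord)
        plddt.append(b)
    if len(chains) > 2:
        raise StructureError(f"{path}: {len(chains)} chains found; only dimers are supported")
    return ComplexModel(
        pair_id=pair_id or path.stem,
        rank=rank,
        chains=chains,
        residue_coords=np.array(coords, dtype=float),
        plddt=np.array(plddt, dtype=float),
    )


# key aliases accepted in score JSON files (ColabFold per-rank dialect plus
# the plain fixture dialect)
_PAE_KEYS = ("pae", "predicted_aligned_error")
_PLDDT_KEYS = ("plddt",)


def read_scores(path, pair_id: str = "", rank: int | None = None) -> ScoreBundle:
    """Read a ColabFold-style score JSON into a :class:`ScoreBundle`.

    The file must contain a PAE matrix, per-residue pLDDT, and scalar
    ``ptm`` and ``iptm``. The legacy AlphaFold ``"iptm+ptm"`` combined key
    is rejected with a pointer to the supported dialect.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc

    pae = next((data[k] for k in _PAE_KEYS if k in data), None)
    if pae is None:
        raise FormatError(f"{path}: missing PAE key (one of {_PAE_KEYS})")
    lengths = {len(row) for row in pae}
    if len(lengths) > 1 or len(pae) not in lengths:
        raise FormatError(f"{path}: PAE matrix is ragged or non-square")
    plddt = next((data[k] for k in _PLDDT_KEYS if k in data), None)
    if plddt is None:
        raise FormatError(f"{path}: missing pLDDT key")
    if "iptm" not in data:
        if "iptm+ptm" in data:
            raise FormatError(
                f"{path}: found legacy 'iptm+ptm' key; only the per-rank ColabFold "
                "dialect with separate 'iptm' and 'ptm' keys is supported"
            )
        raise FormatError(f"{path}: missing 'iptm' key")
    if "ptm" not in data:
        raise FormatError(f"{path}: missing 'ptm' key")

    if rank is None:
        m = re.search(r"rank_(\d{3})", path.name)
        rank = int(m.group(1)) if m else 1
    return ScoreBundle(
        pair_id=pair_id or path.stem,
        rank=rank,
        pae=np.asarray(pae, dtype=float),
        ptm=float(data["ptm"]),
        iptm=float(data["iptm"]),
        plddt=np.asarray(plddt, dtype=float),
    )


def contact_map(model: ComplexModel, cutoff: float = 8.0) -> np.ndarray:
    """Inter-chain residue contact map at a C-beta--C-beta distance cutoff.

    Returns a boolean (len A, len B) matrix; entry (i, j) is True iff the
    representative coordinates of chain-A residue i and chain-B residue j
    are within ``cutoff`` Angstrom (inclusive).
    """
    if len(model.chains) != 2:
        raise StructureError("contact_map requires exactly two chains")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    a = model.residue_coords[model.chain_slice(0)]
    b = model.residue_coords[model.chain_slice(1)]
    return cdist(a, b) <= cutoff


_RANK_RE = re.compile(r"rank_(\d{3})")


def discover_models(directory, pair_id: str, max_rank: int = 5) -> PredictionSet:
    """Discover ranked model/score file pairs for one protein pair.

    Looks for files named ``{pair_id}*rank_00N*`` with coordinate suffixes
    (.pdb/.cif) and score suffix (.json). Duplicate ranks are rejected.
    """
    directory = Path(directory)
    structures: dict[int, Path] = {}
    scores: dict[int, Path] = {}
    for f in sorted(directory.iterdir()):
        if not f.name.startswith(pair_id):
            continue
        m = _RANK_RE.search(f.name)
        if not m:
            continue
        rank = int(m.group(1))
        if rank > max_rank:
            continue
        target = scores if f.suffix == ".json" else structures
        if rank in target:
            raise FormatError(f"duplicate rank {rank} for pair {pair_id} in {directory}")
        target[rank] = f
    ranks = sorted(set(structures) & set(scores))
    if not ranks:
        raise FileNotFoundError(f"no model/score file pairs for {pair_id!r} in {directory}")
    models = []
    for rank in ranks:
        model = read_structure(structures[rank], pair_id=pair_id, rank=rank)
        bundle = read_scores(scores[rank], pair_id=pair_id, rank=rank)
        models.append((model, bundle))
    return PredictionSet(pair_id=pair_id, models=models)
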