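"""Per-residue interface flags and cross-partner interface-frequency profiles.

A residue of the focal chain is a local interaction residue (``lir``) in a
given model if some partner residue places it inside the confident
inter-chain region (symmetrized PAE <= 12 A), and a contact interaction
residue (``clir``) if in addition the same partner residue is within the
8 A C-beta contact cutoff. Aggregating the flags over all predicted
partners of a protein — counting only models with at least one inter-chain
contact — gives the per-residue interface-frequency percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ppikit.afm_io import ScoreBundle
from ppikit.interface_metrics import PAE_CUTOFF, interchain_blocks

__all__ = ["ResidueFlags", "ResidueInterfaceProfile", "residue_flags", "aggregate_profiles"]


@dataclass
class ResidueFlags:
    """Interface membership flags for the focal chain of one model."""

    pair_id: str
    chain: str
    lir: np.ndarray  # bool, per focal-chain residue
    clir: np.ndarray
    n_contacts: int  # inter-chain contact pairs in the model

    def __post_init__(self) -> None:
        self.lir = np.asarray(self.lir, dtype=bool)
        self.clir = np.asarray(self.clir, dtype=bool)
        if self.lir.shape != self.clir.shape:
            raise ValueError("lir and clir must have equal length")
        if np.any(self.clir & ~self.lir):
            raise ValueError("clir implies lir at every residue")


@dataclass
class ResidueInterfaceProfile:
    """Interface-frequency percentages for one protein across partners.

    ``lir_pct[i]`` is 100 x (number of retained partner models in which
    residue i is a lir residue) / ``n_models``; percentages are NaN when
    ``n_models`` is 0.
    """

    gene: str
    sequence: str
    lir_pct: np.ndarray
    clir_pct: np.ndarray
    n_models: int


def residue_flags(
    scores: ScoreBundle,
    contacts: np.ndarray,
    chain_offsets: tuple[int, ...],
    focal_chain: int,
    pae_cutoff: float = PAE_CUTOFF,
) -> ResidueFlags:
    """Flag lir/clir residues of one chain in one model.

    PAE is symmetrized per residue pair with the minimum of the two
    directions. ``clir`` requires the PAE and distance conditions to hold
    for the same partner residue.
    """
    ab, ba = interchain_blocks(scores.pae, chain_offsets)
    sym = np.minimum(ab, ba.T)  # (len A, len B)
    if contacts.shape != sym.shape:
        raise ValueError("contact map does not match inter-chain block")
    conf = sym <= pae_cutoff
    if focal_chain == 0:
        lir = conf.any(axis=1)
        clir = (conf & contacts).any(axis=1)
    elif focal_chain == 1:
        lir = conf.any(axis=0)
        clir = (conf & contacts).any(axis=0)
    else:
        raise ValueError("focal_chain must be 0 or 1")
    return ResidueFlags(
        pair_id=scores.pair_id,
        chain=str(focal_chain),
        lir=lir,
        clir=clir,
        n_contacts=int(contacts.sum()),
    )


def aggregate_profiles(
    flags_per_partner: list[ResidueFlags],
    gene: str = "",
    sequence: str = "",
    min_contacts: int = 1,
) -> ResidueInterfaceProfile:
    """Aggregate per-model flags into interface-frequency percentages.

    Partners whose model has fewer than ``min_contacts`` inter-chain
    contacts are excluded from the denominator. With no retained model the
    percentages are NaN (undefined), not zero.
    """
    if not flags_per_partner:
        raise ValueError("no flags provided")
    n_res = len(flags_per_partner[0].lir)
    for f in flags_per_partner:
        if len(f.lir) != n_res:
            raise ValueError("all flags must refer to the same focal sequence length")
    retained = [f for f in flags_per_partner if f.n_contacts >= min_contacts]
    if not retained:
        nan = np.full(n_res, np.nan)
        return ResidueInterfaceProfile(gene, sequence, nan, nan.copy(), 0)
    lir_counts = np.sum([f.lir for f in retained], axis=0)
    clir_counts = np.sum([f.clir for f in retained], axis=0)
    n = len(retained)
    return ResidueInterfaceProfile(
        gene=gene,
        sequence=sequence,
        lir_pct=100.0 * lir_counts / n,
        clir_pct=100.0 * clir_counts / n,
        n_models=n,
    )
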