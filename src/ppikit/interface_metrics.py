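"""Pair-level interface confidence metrics for predicted dimers.

The central metric is the geometric mean of two component scores computed
from the inter-chain blocks of the PAE matrix:

* ``lis`` — mean of inversely rescaled inter-chain PAE over the confident
  region (PAE <= 12 A), where PAE = 12 maps to 0 and PAE = 0 maps to 1;
* ``clis`` — the same, restricted to residue pairs in direct C-beta contact
  (<= 8 A) within the confident region;
* ``ilis = sqrt(lis * clis)``.

Both are computed per directional inter-chain block (A-rows x B-cols and
B-rows x A-cols) and then averaged over the two blocks; an empty qualifying
set scores 0. Companion metrics (mean inter-chain PAE, its contact-masked
variant, model confidence, pDockQ) are provided for benchmarking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import NamedTuple

import numpy as np

from ppikit.afm_io import ComplexModel, PredictionSet, ScoreBundle, contact_map

__all__ = [
    "InterfaceScore",
    "PairScores",
    "interchain_blocks",
    "compute_lis",
    "compute_clis",
    "compute_ilis",
    "compute_global_metrics",
    "compute_pdockq",
    "score_model",
    "score_pair",
    "plddt_subgroup",
    "PAE_CUTOFF",
    "CONTACT_CUTOFF",
]

PAE_CUTOFF = 12.0
CONTACT_CUTOFF = 8.0

# pDockQ sigmoid constants from the original publication of that metric
PDOCKQ_L = 0.724
PDOCKQ_X0 = 152.611
PDOCKQ_K = 0.052
PDOCKQ_B = 0.018


@dataclass
class InterfaceScore:
    """All pair-level confidence metrics for one model."""

    pair_id: str
    rank: int
    lis: float
    clis: float
    ilis: float
    iptm: float
    ptm: float
    model_confidence: float
    ifpae: float
    ifpae_d8: float  # NaN when the model has no inter-chain contacts
    pdockq: float
    n_lia_pairs: int
    n_contact_pairs: int
    mean_pair_plddt: float
    plddt_subgroup: str


@dataclass
class PairScores:
    """Best-model and across-model-average scores for one pair."""

    pair_id: str
    best: InterfaceScore
    average: InterfaceScore


def plddt_subgroup(mean_plddt: float) -> str:
    """Bin a mean pLDDT into the 0-50 / 50-70 / 70-100 subgroups.

    Boundaries are half-open on the left: [0, 50), [50, 70), [70, 100].
    """
    if mean_plddt < 50:
        return "0-50"
    if mean_plddt < 70:
        return "50-70"
    return "70-100"


def interchain_blocks(pae: np.ndarray, chain_offsets: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Split a full PAE matrix into its two directional inter-chain blocks.

    Returns ``(ab, ba)`` where ``ab`` has shape (len A, len B) (chain-A rows,
    chain-B columns) and ``ba`` has shape (len B, len A).
    """
    if len(chain_offsets) != 2:
        raise ValueError("two chains required")
    n_a = chain_offsets[1]
    ab = pae[:n_a, n_a:]
    ba = pae[n_a:, :n_a]
    return ab, ba


def _block_mean_rescaled(block: np.ndarray, mask: np.ndarray | None, cutoff: float) -> tuple[float, int]:
    """Mean of (cutoff - pae)/cutoff over qualifying entries; 0 if none."""
    qual = block <= cutoff
    if mask is not None:
        qual &= mask
    n = int(qual.sum())
    if n == 0:
        return 0.0, 0
    return float(np.mean((cutoff - block[qual]) / cutoff)), n


def compute_lis(
    scores: ScoreBundle, chain_offsets: tuple[int, ...], pae_cutoff: float = PAE_CUTOFF
) -> tuple[float, int]:
    """Domain-level local interaction score.

    For each directional inter-chain block, entries with PAE <= ``pae_cutoff``
    are rescaled to ``(cutoff - PAE) / cutoff`` and averaged (0 if the block
    has no qualifying entry); the score is the mean of the two block means.

    Returns
    -------
    (lis, n_lia_pairs)
        The score in [0, 1] and the total number of qualifying entries over
        both blocks.
    """
    ab, ba = interchain_blocks(scores.pae, chain_offsets)
    m_ab, n_ab = _block_mean_rescaled(ab, None, pae_cutoff)
    m_ba, n_ba = _block_mean_rescaled(ba, None, pae_cutoff)
    return (m_ab + m_ba) / 2.0, n_ab + n_ba


def compute_clis(
    scores: ScoreBundle,
    contacts: np.ndarray,
    chain_offsets: tuple[int, ...],
    pae_cutoff: float = PAE_CUTOFF,
) -> tuple[float, int]:
    """Contact-filtered local interaction score.

    Identical to :func:`compute_lis` but qualifying entries must additionally
    be in direct inter-chain contact; the same (len A, len B) contact mask is
    applied to both PAE directions.

    Returns
    -------
    (clis, n_contact_pairs)
        The score in [0, 1] and the number of contacting residue pairs.
    """
    ab, ba = interchain_blocks(scores.pae, chain_offsets)
    if contacts.shape != ab.shape:
        raise ValueError(
            f"contact map shape {contacts.shape} does not match inter-chain block {ab.shape}"
        )
    m_ab, _ = _block_mean_rescaled(ab, contacts, pae_cutoff)
    m_ba, _ = _block_mean_rescaled(ba, contacts.T, pae_cutoff)
    return (m_ab + m_ba) / 2.0, int(contacts.sum())


def compute_ilis(lis: float, clis: float) -> float:
    """Geometric mean sqrt(lis * clis)."""
    if not (0.0 <= lis <= 1.0 and 0.0 <= clis <= 1.0):
        raise ValueError("lis and clis must lie in [0, 1]")
    return math.sqrt(lis * clis)


class GlobalMetrics(NamedTuple):
    ifpae: float
    ifpae_d8: float
    model_confidence: float
    mean_pair_plddt: float
    plddt_subgroup: str


def compute_global_metrics(
    scores: ScoreBundle, contacts: np.ndarray, chain_offsets: tuple[int, ...]
) -> GlobalMetrics:
    """Global companion metrics for one model.

    ``ifpae`` is the mean over all entries of both inter-chain PAE blocks;
    ``ifpae_d8`` restricts to contact-masked entries (NaN when there is no
    contact); ``model_confidence`` is ``0.8 * iptm + 0.2 * ptm``;
    ``mean_pair_plddt`` averages per-residue pLDDT over both chains.
    """
    ab, ba = interchain_blocks(scores.pae, chain_offsets)
    ifpae = float((ab.sum() + ba.sum()) / (ab.size + ba.size))
    n_contacts = int(contacts.sum())
    if n_contacts == 0:
        ifpae_d8 = float("nan")
    else:
        ifpae_d8 = float((ab[contacts].sum() + ba[contacts.T].sum()) / (2 * n_contacts))
    mean_plddt = float(np.mean(scores.plddt))
    return GlobalMetrics(
        ifpae=ifpae,
        ifpae_d8=ifpae_d8,
        model_confidence=0.8 * scores.iptm + 0.2 * scores.ptm,
        mean_pair_plddt=mean_plddt,
        plddt_subgroup=plddt_subgroup(mean_plddt),
    )


def compute_pdockq(contacts: np.ndarray, plddt: np.ndarray, chain_offsets: tuple[int, ...]) -> float:
    """Sigmoid pDockQ score (optional, benchmark-parity only).

    ``x = mean pLDDT of interface residues * log10(number of contacts)``,
    where interface residues have at least one inter-chain contact at 8 A.
    Zero contacts return the sigmoid's lower asymptote.
    """
    n_contacts = int(contacts.sum())
    if n_contacts == 0:
        return PDOCKQ_B
    n_a = chain_offsets[1]
    iface_a = np.flatnonzero(contacts.any(axis=1))
    iface_b = np.flatnonzero(contacts.any(axis=0)) + n_a
    mean_if_plddt = float(np.mean(plddt[np.concatenate([iface_a, iface_b])]))
    x = mean_if_plddt * math.log10(n_contacts)
    return PDOCKQ_L / (1.0 + math.exp(-PDOCKQ_K * (x - PDOCKQ_X0))) + PDOCKQ_B


def score_model(model: ComplexModel, scores: ScoreBundle) -> InterfaceScore:
    """Compute every metric for a single (model, score bundle) pair."""
    contacts = contact_map(model, CONTACT_CUTOFF)
    offsets = model.chain_offsets
    lis, n_lia = compute_lis(scores, offsets)
    clis, n_contact = compute_clis(scores, contacts, offsets)
    g = compute_global_metrics(scores, contacts, offsets)
    return InterfaceScore(
        pair_id=model.pair_id,
        rank=model.rank,
        lis=lis,
        clis=clis,
        ilis=compute_ilis(lis, clis),
        iptm=scores.iptm,
        ptm=scores.ptm,
        model_confidence=g.model_confidence,
        ifpae=g.ifpae,
        ifpae_d8=g.ifpae_d8,
        pdockq=compute_pdockq(contacts, scores.plddt, offsets),
        n_lia_pairs=n_lia,
        n_contact_pairs=n_contact,
        mean_pair_plddt=g.mean_pair_plddt,
        plddt_subgroup=g.plddt_subgroup,
    )


_NUMERIC_FIELDS = [
    "lis",
    "clis",
    "ilis",
    "iptm",
    "ptm",
    "model_confidence",
    "ifpae",
    "ifpae_d8",
    "pdockq",
    "n_lia_pairs",
    "n_contact_pairs",
    "mean_pair_plddt",
]


def score_pair(pred: PredictionSet) -> PairScores:
    """Score all models of a pair; report the rank-1 model and the mean.

    The "best" record is the rank-1 model as ranked by the prediction
    pipeline (not the max-scoring model). The "average" record holds the
    per-metric arithmetic mean over all provided models; ``ifpae_d8``
    averages over models where it is defined (NaN-mean).
    """
    if not pred.models:
        raise ValueError("prediction set is empty")
    per_model = [score_model(m, s) for m, s in pred.models]
    best = per_model[0]
    if best.rank != 1:
        raise ValueError(f"best model must have rank 1, got {best.rank}")
    avg_kwargs = {}
    for name in _NUMERIC_FIELDS:
        values = np.array([getattr(s, name) for s in per_model], dtype=float)
        avg_kwargs[name] = float(np.nanmean(values)) if name == "ifpae_d8" else float(np.mean(values))
    avg_kwargs["n_lia_pairs"] = int(round(avg_kwargs["n_lia_pairs"]))
    avg_kwargs["n_contact_pairs"] = int(round(avg_kwargs["n_contact_pairs"]))
    average = InterfaceScore(
        pair_id=pred.pair_id,
        rank=0,
        plddt_subgroup=plddt_subgroup(avg_kwargs["mean_pair_plddt"]),
        **avg_kwargs,
    )
    return PairScores(pair_id=pred.pair_id, best=best, average=average)


def scores_to_row(pair: PairScores) -> dict:
    """Flatten a PairScores into one TSV row with best_*/avg_* columns."""
    row: dict = {"pair_id": pair.pair_id}
    for prefix, rec in (("best", pair.best), ("avg", pair.average)):
        for f in fields(InterfaceScore):
            if f.name in ("pair_id", "rank"):
                continue
            row[f"{prefix}_{f.name}"] = getattr(rec, f.name)
    return row
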