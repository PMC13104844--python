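"""Missense-allele enrichment at predicted interaction interfaces.

A residue table (one row per residue per gene, with interface-frequency
percentages, conservation scores and a mutation indicator) is binned by
interface frequency, tested for a monotone trend in mutation rate
(Cochran-Armitage), validated by within-gene permutation to control
gene-level ascertainment, stratified by conservation, and modelled by
logistic regression.

Residue tables are pandas DataFrames with columns ``gene``, ``position``
(1-based), ``aa``, ``lir_pct``, ``clir_pct``, ``phylop`` and boolean
``mutated``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MutationRecord",
    "global_align",
    "map_mutation",
    "MappingResult",
    "bin_by_lir",
    "BIN_LABELS",
    "enrichment_rates",
    "category_rates",
    "cochran_armitage",
    "within_gene_permutation",
    "PermutationResult",
    "conservation_analysis",
    "ConservationResult",
]

BIN_LABELS = ("Zero", "Q1", "Q2", "Q3", "Q4")

_AA = set("ACDEFGHIKLMNPQRSTVWYX")  # X = unknown residue, never treated specially


@dataclass(frozen=True)
class MutationRecord:
    """One missense mutation: gene, 1-based position, ref/alt amino acid."""

    gene: str
    position: int
    ref_aa: str
    alt_aa: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt amino acids must differ")


# ---------------------------------------------------------------------------
# Needleman-Wunsch global alignment and position mapping
# ---------------------------------------------------------------------------

def global_align(
    seq_a: str, seq_b: str, match: int = 1, mismatch: int = -1, gap: int = -1
) -> tuple[list[tuple[int | None, int | None]], int]:
    """Optimal global alignment with linear gap penalty.

    Scoring defaults to identity +1 / mismatch -1 / gap -1. Traceback
    tie-breaking is deterministic: diagonal, then up (gap in ``seq_b``),
    then left.

    Returns
    -------
    (pairs, score)
        ``pairs`` is the aligned column list of 0-based indices, ``None``
        marking a gap.
    """
    for seq in (seq_a, seq_b):
        bad = set(seq) - _AA
        if bad:
            raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    n, m = len(seq_a), len(seq_b)
    score = np.empty((n + 1, m + 1), dtype=np.int64)
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(b == a[i - 1], match, mismatch)
        prev, cur = score[i - 1], score[i]
        # rowwise DP; the left-dependency forces a scalar loop
        for j in range(1, m + 1):
            cur[j] = max(prev[j - 1] + sub[j - 1], prev[j] + gap, cur[j - 1] + gap)
    pairs: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            match if seq_a[i - 1] == seq_b[j - 1] else mismatch
        ):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    return pairs, int(score[n, m])


@dataclass
class MappingResult:
    accepted: bool
    position: int | None = None  # 1-based position in the model sequence
    reason: str = ""


def map_mutation(
    rec: MutationRecord, model_sequence: str, annotation_sequence: str | None = None
) -> MappingResult:
    """Map a mutation onto a model sequence, with alignment-based correction.

    Exact match of the reference amino acid at the stated position is
    accepted directly. Otherwise the annotation sequence (the numbering the
    mutation refers to) is globally aligned to the model sequence and the
    position transferred through the alignment; the mapping is accepted only
    if the model residue at the transferred position equals the reference
    amino acid.
    """
    pos0 = rec.position - 1
    if pos0 < len(model_sequence) and model_sequence[pos0] == rec.ref_aa:
        return MappingResult(True, rec.position)
    if annotation_sequence is None:
        if pos0 >= len(model_sequence):
            return MappingResult(False, reason="out-of-range")
        return MappingResult(False, reason="ref-mismatch")
    if pos0 >= len(annotation_sequence):
        return MappingResult(False, reason="out-of-range")
    pairs, _ = global_align(annotation_sequence, model_sequence)
    transfer = {i: j for i, j in pairs if i is not None}
    j = transfer.get(pos0)
    if j is None:
        return MappingResult(False, reason="gap")
    if model_sequence[j] != rec.ref_aa:
        return MappingResult(False, reason="ref-mismatch")
    return MappingResult(True, j + 1)


# ---------------------------------------------------------------------------
# Binning and rates
# ---------------------------------------------------------------------------

def bin_by_lir(
    table: pd.DataFrame, field: str = "lir_pct", domain_only: bool = False
) -> pd.DataFrame:
    """Assign each residue to Zero or a pooled nonzero quartile bin.

    The Zero bin holds residues with ``field`` exactly 0. Quartile edges are
    the 25/50/75th percentiles of the pooled nonzero values across all
    genes; bins are right-closed (value == edge falls in the lower bin).
    With ``domain_only`` the table is first restricted to residues inside
    some interaction domain (``lir_pct > 0``).

    Returns a copy with a ``lir_bin`` column (Zero, Q1..Q4).
    """
    out = table.copy()
    if domain_only:
        out = out[out["lir_pct"] > 0].copy()
    vals = out[field].to_numpy(dtype=float)
    nonzero = vals[vals > 0]
    bins = np.full(len(out), "Zero", dtype=object)
    if len(nonzero) == 0:
        warnings.warn(f"all {field} values are zero; only the Zero bin is populated", stacklevel=2)
    else:
        edges = np.percentile(nonzero, [25, 50, 75])
        # right-closed: v <= q25 -> Q1, q25 < v <= q50 -> Q2, ...
        q = np.searchsorted(edges, vals[vals > 0], side="left")
        bins[vals > 0] = np.array(["Q1", "Q2", "Q3", "Q4"], dtype=object)[q]
    out["lir_bin"] = pd.Categorical(bins, categories=list(BIN_LABELS), ordered=True)
    return out


def enrichment_rates(binned: pd.DataFrame) -> pd.DataFrame:
    """Per-bin mutation counts, rates, and fold enrichment versus Zero."""
    g = binned.groupby("lir_bin", observed=False)
    df = pd.DataFrame(
        {
            "n_residues": g.size(),
            "n_mutated": g["mutated"].sum().astype(int),
        }
    )
    df["rate"] = np.where(df["n_residues"] > 0, df["n_mutated"] / df["n_residues"], np.nan)
    zero_rate = df.loc["Zero", "rate"] if "Zero" in df.index else np.nan
    df["fold_vs_zero"] = df["rate"] / zero_rate if zero_rate and zero_rate > 0 else np.nan
    return df


def category_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Mutation rates for the No-LIR / LIR-minus-cLIR / cLIR residue split."""
    cat = np.where(
        table["lir_pct"] == 0,
        "No LIR",
        np.where(table["clir_pct"] > 0, "cLIR", "LIR-cLIR"),
    )
    g = table.groupby(pd.Categorical(cat, categories=["No LIR", "LIR-cLIR", "cLIR"], ordered=True),
                      observed=False)
    df = pd.DataFrame({"n_residues": g.size(), "n_mutated": g["mutated"].sum().astype(int)})
    df["rate"] = np.where(df["n_residues"] > 0, df["n_mutated"] / df["n_residues"], np.nan)
    return df


# ---------------------------------------------------------------------------
# Trend and permutation tests
# ---------------------------------------------------------------------------

def cochran_armitage(mutated, totals, scores=None) -> tuple[float, float]:
    """Cochran-Armitage test for trend in proportions across ordered bins.

    ``T = sum_i s_i (m_i - n_i * pbar)`` with variance under the
    hypergeometric (permutation) null, including the finite-population
    factor N/(N-1). Returns (Z, two-sided normal p).
    """
    m = np.asarray(mutated, dtype=float)
    n = np.asarray(totals, dtype=float)
    if m.shape != n.shape or m.ndim != 1:
        raise ValueError("mutated and totals must be equal-length vectors")
    keep = n > 0
    s = np.arange(len(n), dtype=float) if scores is None else np.asarray(scores, dtype=float)
    m, n, s = m[keep], n[keep], s[keep]
    if len(n) < 2:
        raise ValueError("need at least two non-empty bins")
    N = n.sum()
    pbar = m.sum() / N
    T = float(np.sum(s * (m - n * pbar)))
    var = pbar * (1 - pbar) * (N / (N - 1)) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / N)
    if var <= 0:
        raise ValueError("degenerate table: zero trend variance")
    z = T / np.sqrt(var)
    return z, float(2 * norm.sf(abs(z)))


def _trend_z_from_counts(mutated_by_bin: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Vectorized trend Z for (n_perm, k) permuted per-bin mutated counts."""
    n = totals.astype(float)
    keep = n > 0
    n = n[keep]
    m = mutated_by_bin[:, keep].astype(float)
    s = np.flatnonzero(keep).astype(float)  # scores follow the original bin order
    N = n.sum()
    pbar = m.sum(axis=1) / N
    T = m @ s - pbar * np.sum(n * s)
    var = pbar * (1 - pbar) * (N / (N - 1)) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / N)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var > 0, T / np.sqrt(var), 0.0)


def _top_fold_from_counts(mutated_by_bin: np.ndarray, totals: np.ndarray) -> np.ndarray:
    n = totals.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = mutated_by_bin / n
        return np.where(rates[:, 0] > 0, rates[:, -1] / rates[:, 0], np.inf)


_STATISTICS = {"trend_z": _trend_z_from_counts, "top_bin_fold": _top_fold_from_counts}


@dataclass
class PermutationResult:
    p: float
    observed: float
    n_perm: int
    null: np.ndarray = field(repr=False, default=None)


def within_gene_permutation(
    binned: pd.DataFrame,
    statistic: str = "trend_z",
    n_perm: int = 100_000,
    seed: int | None = None,
    alternative: str = "greater",
    return_null: bool = False,
) -> PermutationResult:
    """Permutation test shuffling mutation positions within each gene.

    Each permutation reassigns every gene's mutated positions uniformly
    without replacement among that gene's residues (per-gene mutation counts
    fixed), recomputes the statistic from the permuted per-bin counts, and
    compares to the observed value. The p-value uses the add-one estimator
    ``(1 + #{perm >= observed}) / (1 + n_perm)`` (one-sided, enrichment
    direction, by default).

    The table must already carry a ``lir_bin`` column (bins are functions of
    the fixed interface percentages and do not change under permutation).

    ``statistic`` is ``"trend_z"``, ``"top_bin_fold"``, or a callable
    mapping a (n_perm, n_bins) matrix of permuted per-bin mutated counts and
    the per-bin totals to a vector of statistics.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stat_fn = _STATISTICS.get(statistic, statistic)
    if not callable(stat_fn):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    bin_codes = binned["lir_bin"].cat.codes.to_numpy()
    k = len(binned["lir_bin"].cat.categories)
    totals = np.bincount(bin_codes, minlength=k)
    mutated = binned["mutated"].to_numpy(dtype=bool)
    observed_counts = np.bincount(bin_codes[mutated], minlength=k)[None, :]
    observed = float(stat_fn(observed_counts, totals)[0])

    null_counts = np.zeros((n_perm, k), dtype=np.int64)
    for _, sub in binned.groupby("gene", sort=False):
        m_g = int(sub["mutated"].sum())
        if m_g == 0:
            continue
        gene_bins = np.bincount(sub["lir_bin"].cat.codes.to_numpy(), minlength=k)
        if m_g > gene_bins.sum():
            raise ValueError("gene has more mutations than residues")
        null_counts += rng.multivariate_hypergeometric(gene_bins, m_g, size=n_perm)
    null = np.asarray(stat_fn(null_counts, totals), dtype=float)

    if alternative == "greater":
        hits = int(np.sum(null >= observed))
    elif alternative == "less":
        hits = int(np.sum(null <= observed))
    elif alternative == "two-sided":
        hits = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + hits) / (1 + n_perm)
    return PermutationResult(p=p, observed=observed, n_perm=n_perm,
                             null=null if return_null else None)


# ---------------------------------------------------------------------------
# Conservation stratification and logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ConservationResult:
    strata: pd.DataFrame
    beta_clir_only: float
    beta_clir_adjusted: float
    beta_phylop: float
    p_clir_adjusted: float
    p_phylop: float
    attenuation: float
    n_excluded_missing_phylop: int
    converged: bool
    penalized: bool
    params_adjusted: np.ndarray = field(repr=False, default=None)
    bse_adjusted: np.ndarray = field(repr=False, default=None)


def _logit_fit(X: np.ndarray, y: np.ndarray):
    """Newton/IRLS logistic fit via statsmodels; penalized fallback."""
    import statsmodels.api as sm

    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False, tol=1e-8, maxiter=200)
        if res.mle_retvals.get("converged", False):
            return res, True, False
    except Exception:
        pass
    res = model.fit_regularized(disp=False, alpha=1e-4, maxiter=500)
    return res, False, True


def conservation_analysis(table: pd.DataFrame, clir_binary: bool = False) -> ConservationResult:
    """Conservation-stratified interface enrichment and adjusted regression.

    Residues lacking a conservation score are excluded (count reported).
    Residues are stratified into pooled conservation quartiles; within each
    stratum the contact-interface fold enrichment compares mutation rates of
    ``clir_pct > 0`` versus ``clir_pct == 0`` residues. Logistic regression
    ``mutated ~ clir + phylop`` (and a clir-only reference fit) yields Wald
    p-values and the attenuation fraction
    ``1 - beta_clir(adjusted) / beta_clir(clir-only)``.
    """
    n_missing = int(table["phylop"].isna().sum())
    t = table.dropna(subset=["phylop"]).copy()
    if t.empty:
        raise ValueError("no residues with conservation scores")
    phylop = t["phylop"].to_numpy(dtype=float)
    clir = t["clir_pct"].to_numpy(dtype=float)
    if clir_binary:
        clir = (clir > 0).astype(float)
    if np.ptp(clir) == 0:
        raise ValueError("clir predictor is constant; coefficient inestimable")
    y = t["mutated"].to_numpy(dtype=float)

    edges = np.percentile(phylop, [25, 50, 75])
    stratum = np.searchsorted(edges, phylop, side="left")
    rows = []
    for s in range(4):
        sel = stratum == s
        iface = sel & (t["clir_pct"].to_numpy() > 0)
        noniface = sel & (t["clir_pct"].to_numpy() == 0)
        r_if = y[iface].mean() if iface.any() else np.nan
        r_no = y[noniface].mean() if noniface.any() else np.nan
        rows.append(
            {
                "stratum": f"P{s + 1}",
                "n_interface": int(iface.sum()),
                "n_noninterface": int(noniface.sum()),
                "rate_interface": r_if,
                "rate_noninterface": r_no,
                "fold": r_if / r_no if r_no and r_no > 0 else np.nan,
            }
        )
    strata = pd.DataFrame(rows)

    ones = np.ones_like(clir)
    res_only, conv1, pen1 = _logit_fit(np.column_stack([ones, clir]), y)
    res_adj, conv2, pen2 = _logit_fit(np.column_stack([ones, clir, phylop]), y)
    b1_only = float(res_only.params[1])
    b1_adj = float(res_adj.params[1])
    b2 = float(res_adj.params[2])
    attenuation = 1.0 - b1_adj / b1_only if b1_only != 0 else np.nan
    pvals = np.asarray(res_adj.pvalues, dtype=float)
    return ConservationResult(
        strata=strata,
        beta_clir_only=b1_only,
        beta_clir_adjusted=b1_adj,
        beta_phylop=b2,
        p_clir_adjusted=float(pvals[1]),
        p_phylop=float(pvals[2]),
        attenuation=float(attenuation),
        n_excluded_missing_phylop=n_missing,
        converged=conv1 and conv2,
        penalized=pen1 or pen2,
        params_adjusted=np.asarray(res_adj.params, dtype=float),
        bse_adjusted=np.asarray(res_adj.bse, dtype=float),
    )
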