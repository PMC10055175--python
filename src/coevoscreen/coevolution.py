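"""Pairwise coevolution statistic over phylogeny-ordered phyletic profiles.

Two genes that were repeatedly gained or lost together during evolution
leave correlated presence/absence patterns.  With genomes arranged in a
fixed phylogeny-derived order, each gene's profile becomes a binary vector,
and every boundary between adjacent genomes either carries a transition
(0->1 gain, 1->0 loss) or not.  The statistic counts, for a gene pair,
boundaries where both genes transition in the same direction (concordant —
a simultaneous gain or simultaneous loss), boundaries where only one does,
and boundaries where neither does; double transitions with opposite signs
are discordant and are excluded from the 2x2 table rather than counted as
concordant.  Enrichment of concordance is assessed with a one-sided Fisher
exact test, and the family of all tested pairs is Bonferroni-corrected.

The screen is linear-order-based by design: no ancestral-state
reconstruction and no tree-aware gain/loss mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "ConcordanceTable",
    "PairAssociation",
    "compute_transitions",
    "transition_matrix",
    "concordance_table",
    "fisher_exact_one_sided",
    "bonferroni_adjust",
    "screen_all_pairs",
    "top_k_partners",
    "associations_to_frame",
    "DEFAULT_ALPHA",
    "DEFAULT_MIN_TRANSITIONS",
]

DEFAULT_ALPHA = 0.001
DEFAULT_MIN_TRANSITIONS = 1


@dataclass(frozen=True, slots=True)
class ConcordanceTable:
    """2x2 concordance table over adjacent-genome boundaries for one pair.

    ``a``: both genes transition with equal sign (concordant);
    ``b``/``c``: only gene A / only gene B transitions;
    ``d``: neither transitions;
    ``disc``: both transition with opposite signs — discordant boundaries,
    kept out of the 2x2 table and reported separately.
    a + b + c + d + disc equals the number of boundaries (N - 1).
    """

    a: int
    b: int
    c: int
    d: int
    disc: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d, self.disc) < 0:
            raise ValueError(f"negative count in {self}")

    @property
    def n_boundaries(self) -> int:
        return self.a + self.b + self.c + self.d + self.disc


@dataclass(frozen=True, slots=True)
class PairAssociation:
    """Association result for one unordered gene pair."""

    gene_a: str
    gene_b: str
    table: ConcordanceTable
    p_raw: float
    p_adj: float
    significant: bool


def compute_transitions(profile_row: np.ndarray) -> np.ndarray:
    """Signed transition vector of a binary profile.

    Entry i covers the boundary between genome i and genome i+1 (canonical
    order): +1 for a gain (0->1), -1 for a loss (1->0), 0 for no change.
    """
    row = np.asarray(profile_row)
    if row.ndim != 1 or row.size < 2:
        raise ValueError("profile must be a 1-D vector of length >= 2")
    if not np.isin(row, (0, 1)).all():
        bad = row[~np.isin(row, (0, 1))][0]
        raise ValueError(f"non-binary profile entry: {bad!r}")
    return np.diff(row.astype(np.int8))


def transition_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Signed transition vectors for every gene (rows) at once.

    Columns are boundary labels ``"<left>|<right>"`` between adjacent
    genomes of the canonical order.
    """
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("profile matrix contains non-binary entries")
    trans = np.diff(values.astype(np.int8), axis=1)
    boundaries = [f"{l}|{r}" for l, r in zip(matrix.columns[:-1], matrix.columns[1:])]
    return pd.DataFrame(trans, index=matrix.index, columns=boundaries)


def concordance_table(t_a: np.ndarray, t_b: np.ndarray) -> ConcordanceTable:
    """Concordance table of two signed transition vectors of equal length."""
    t_a = np.asarray(t_a, dtype=np.int8)
    t_b = np.asarray(t_b, dtype=np.int8)
    if t_a.shape != t_b.shape:
        raise ValueError(f"length mismatch: {t_a.shape} vs {t_b.shape}")
    nz_a = t_a != 0
    nz_b = t_b != 0
    both = nz_a & nz_b
    a = int(np.sum(both & (t_a == t_b)))
    disc = int(np.sum(both) - a)
    b = int(np.sum(nz_a & ~nz_b))
    c = int(np.sum(~nz_a & nz_b))
    d = int(np.sum(~nz_a & ~nz_b))
    return ConcordanceTable(a=a, b=b, c=c, d=d, disc=disc)


def fisher_exact_one_sided(table: ConcordanceTable) -> float:
    """One-sided (concordance-enrichment) Fisher exact P for a 2x2 table.

    P = sum over a' >= a of the hypergeometric probability with the table's
    margins.  Degenerate tables (a zero row or column margin) give P = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    m = a + b + c + d
    if m == 0:
        return 1.0
    # population m, a+b "successes" (gene A transitions), a+c draws
    return float(hypergeom.sf(a - 1, m, a + b, a + c))


def bonferroni_adjust(raw_pvalues, m: int):
    """Bonferroni adjustment: min(1, m * p) per value; order-preserving."""
    if m < 1:
        raise ValueError(f"number of tests m must be >= 1, got {m}")
    raw = np.asarray(raw_pvalues, dtype=float)
    return np.minimum(1.0, m * raw)


def _pairwise_counts(trans: np.ndarray):
    """All-pairs concordance counts via integer matrix products.

    For signed transition matrix T (genes x boundaries) with indicator
    NZ = (T != 0):  NZ @ NZ.T counts double transitions and T @ T.T counts
    concordant minus discordant ones, so a and disc fall out of their sum
    and difference.  Returns square arrays (a, b, c, d, disc).
    """
    t = trans.astype(np.float64)
    nz = (trans != 0).astype(np.float64)
    both = np.rint(nz @ nz.T).astype(np.int64)
    sgn = np.rint(t @ t.T).astype(np.int64)
    a = (both + sgn) // 2
    disc = (both - sgn) // 2
    totals = np.rint(nz.sum(axis=1)).astype(np.int64)
    b = totals[:, None] - a - disc
    c = totals[None, :] - a - disc
    d = trans.shape[1] - a - b - c - disc
    return a, b, c, d, disc


def _fisher_sf_array(a, b, c, d):
    m = a + b + c + d
    with np.errstate(invalid="ignore"):
        p = hypergeom.sf(a - 1, m, a + b, a + c)
    return np.where(m == 0, 1.0, p)


def _eligible_genes(matrix: pd.DataFrame, min_transitions: int) -> pd.DataFrame:
    trans = transition_matrix(matrix)
    n_trans = (trans.to_numpy() != 0).sum(axis=1)
    return trans.loc[n_trans >= min_transitions]


def screen_all_pairs(
    matrix: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_transitions: int = DEFAULT_MIN_TRANSITIONS,
    m_override: int | None = None,
) -> list[PairAssociation]:
    """Test every gene pair for concordant gain/loss transitions.

    Genes with fewer than ``min_transitions`` transitions are excluded
    before pairing (a gene that never changed state is untestable).  The
    Bonferroni family size m defaults to the number of pairs actually
    tested; ``m_override`` substitutes a stricter family size (e.g. the
    unfiltered G*(G-1)/2).

    Returns associations sorted by adjusted P, then by gene pair.
    """
    trans = _eligible_genes(matrix, min_transitions)
    genes = list(trans.index)
    g = len(genes)
    if g < 2:
        raise ValueError(
            f"fewer than 2 genes left after the transition filter ({g})"
        )

    a, b, c, d, disc = _pairwise_counts(trans.to_numpy())
    iu, ju = np.triu_indices(g, k=1)
    p_raw = _fisher_sf_array(a[iu, ju], b[iu, ju], c[iu, ju], d[iu, ju])

    m = len(iu) if m_override is None else m_override
    if m_override is not None and m_override < len(iu):
        raise ValueError("m_override smaller than the number of tested pairs")
    p_adj = bonferroni_adjust(p_raw, m)

    pairs = []
    for k in range(len(iu)):
        i, j = int(iu[k]), int(ju[k])
        table = ConcordanceTable(
            a=int(a[i, j]), b=int(b[i, j]), c=int(c[i, j]),
            d=int(d[i, j]), disc=int(disc[i, j]),
        )
        pairs.append(
            PairAssociation(
                gene_a=genes[i],
                gene_b=genes[j],
                table=table,
                p_raw=float(p_raw[k]),
                p_adj=float(p_adj[k]),
                significant=bool(p_adj[k] < alpha),
            )
        )
    pairs.sort(key=lambda p: (p.p_adj, p.p_raw, p.gene_a, p.gene_b))
    return pairs


def top_k_partners(
    matrix: pd.DataFrame,
    query_gene: str,
    k: int,
    min_transitions: int = DEFAULT_MIN_TRANSITIONS,
) -> list[tuple[str, float]]:
    """Rank the query's coevolution partners by ascending raw Fisher P.

    Ties are broken by descending concordant count a, then by
    lexicographic gene identifier.  Returns at most k (gene, raw P) pairs;
    fewer if fewer genes are eligible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if query_gene not in matrix.index:
        raise KeyError(f"unknown query gene {query_gene!r}")
    trans = _eligible_genes(matrix, min_transitions)
    if query_gene not in trans.index:
        raise ValueError(
            f"query gene {query_gene!r} excluded by the transition filter"
        )
    others = [g for g in trans.index if g != query_gene]
    if not others:
        return []
    tq = trans.loc[query_gene].to_numpy()
    to = trans.loc[others].to_numpy()

    nz_q = tq != 0
    nz_o = to != 0
    both = nz_o & nz_q[None, :]
    a = ((both & (to == tq[None, :])).sum(axis=1)).astype(np.int64)
    disc = both.sum(axis=1) - a
    b = nz_q.sum() - a - disc
    c = nz_o.sum(axis=1) - a - disc
    d = len(tq) - a - b - c - disc
    p_raw = _fisher_sf_array(a, b, c, d)

    ranked = sorted(
        zip(others, p_raw, a),
        key=lambda t: (t[1], -t[2], t[0]),
    )
    return [(g, float(p)) for g, p, _ in ranked[:k]]


def associations_to_frame(pairs: list[PairAssociation]) -> pd.DataFrame:
    """Tabulate associations (one row per pair, screen output format)."""
    return pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in pairs],
            "gene_b": [p.gene_b for p in pairs],
            "a": [p.table.a for p in pairs],
            "b": [p.table.b for p in pairs],
            "c": [p.table.c for p in pairs],
            "d": [p.table.d for p in pairs],
            "disc": [p.table.disc for p in pairs],
            "p_raw": [p.p_raw for p in pairs],
            "p_adj": [p.p_adj for p in pairs],
            "significant": [p.significant for p in pairs],
        }
    )
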