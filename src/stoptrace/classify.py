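"""Cell classification and exact contingency statistics.

Each cell × behavior is labeled excited / inhibited / uncorrelated from its
shuffle-test flags.  Group composition (e.g. medial vs lateral implant
location × three classes) is compared with the Freeman–Halton extension of
Fisher's exact test to r×c tables: the two-sided P is the total
multivariate-hypergeometric probability of all tables sharing the observed
margins whose probability does not exceed that of the observed table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .events import ResamplingResult

logger = logging.getLogger(__name__)

CLASS_EXCITED = "excited"
CLASS_INHIBITED = "inhibited"
CLASS_UNCORRELATED = "uncorrelated"
CLASS_ORDER = (CLASS_EXCITED, CLASS_INHIBITED, CLASS_UNCORRELATED)


def classify_cell(result: ResamplingResult) -> str:
    """Three-way class label from the resampling-test flags.

    If both flags are set (possible since excitation and inhibition are
    tested separately — a tonically active cell suppressed at stops sits
    above the session average just before them), the direction whose
    observed statistic is more extreme against its null wins: first by
    shuffle percentile, then — since percentiles saturate at 100 with a
    finite shuffle count — by exceedance in null SDs.  The conflict is
    logged.
    """
    if result.excited and result.inhibited:
        key_exc = (result.max_percentile, getattr(result, "z_max", 0.0))
        key_inh = (result.min_percentile, getattr(result, "z_min", 0.0))
        label = CLASS_EXCITED if key_exc >= key_inh else CLASS_INHIBITED
        logger.warning(
            "cell flagged both excited (max pct %.2f) and inhibited (min pct %.2f); "
            "assigned '%s' by extremity",
            result.max_percentile,
            result.min_percentile,
            label,
        )
        return label
    if result.excited:
        return CLASS_EXCITED
    if result.inhibited:
        return CLASS_INHIBITED
    return CLASS_UNCORRELATED


def _log_table_prob(cells: np.ndarray, lg_margins: float, lg_total: float) -> float:
    return lg_margins - lg_total - math.fsum(math.lgamma(v + 1.0) for v in cells.ravel())


def _iter_tables(row_sums, col_sums):
    """Yield every nonnegative integer table with the given margins."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=int)

    def fill_row(i, remaining_cols):
        if i == r - 1:
            table[i] = remaining_cols
            yield table
            return
        def fill_cell(j, left_in_row, rem):
            if j == c - 1:
                if left_in_row <= rem[j]:
                    table[i, j] = left_in_row
                    new_rem = rem.copy()
                    new_rem[j] -= left_in_row
                    yield from fill_row(i + 1, new_rem)
                return
            hi = min(left_in_row, rem[j])
            for v in range(hi + 1):
                table[i, j] = v
                new_rem = rem.copy()
                new_rem[j] -= v
                yield from fill_cell(j + 1, left_in_row - v, new_rem)
        yield from fill_cell(0, row_sums[i], remaining_cols)

    yield from fill_row(0, np.asarray(col_sums, dtype=int))


def fisher_exact_rxc(table, max_total: int = 200, tie_tol: float = 1e-12) -> float:
    """Two-sided Freeman–Halton exact P for an r×c contingency table.

    Enumerates every table with the observed margins and sums the
    probabilities of those at most as probable as the observed one
    (relative log tolerance ``tie_tol`` for ties).  All-zero rows and
    columns are dropped with a warning.  Totals beyond ``max_total``
    are rejected rather than approximated.
    """
    t = np.asarray(table)
    if t.ndim != 2:
        raise InputError("contingency table must be 2-D")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise InputError("contingency table must hold integers")
        t = np.round(t).astype(int)
    if np.any(t < 0):
        raise InputError("contingency table must be nonnegative")
    keep_rows = t.sum(axis=1) > 0
    keep_cols = t.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        logger.warning("dropping all-zero rows/columns from contingency table")
        t = t[keep_rows][:, keep_cols]
    n = int(t.sum())
    if n == 0:
        raise InputError("contingency table is empty")
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    if n > max_total:
        raise InputError(
            f"table total {n} exceeds the exhaustive-enumeration bound {max_total}"
        )

    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    lg_margins = math.fsum(math.lgamma(v + 1.0) for v in np.concatenate([row_sums, col_sums]))
    lg_total = math.lgamma(n + 1.0)
    logp_obs = _log_table_prob(t, lg_margins, lg_total)

    total = 0.0
    for cand in _iter_tables(row_sums, col_sums):
        logp = _log_table_prob(cand, lg_margins, lg_total)
        if logp <= logp_obs + tie_tol:
            total += math.exp(logp)
    return min(1.0, total)


def composition_test(
    cells: pd.DataFrame,
    group_by: str = "location",
    class_col: str = "cell_class",
    max_total: int = 200,
):
    """Group × class contingency table and its Freeman–Halton exact P.

    ``cells`` holds one row per cell with a group column (implant location
    by default) and a class column; the table orders classes
    excited/inhibited/uncorrelated.
    """
    if cells.empty:
        raise InputError("empty cell set")
    groups = sorted(cells[group_by].unique())
    classes = [c for c in CLASS_ORDER if c in set(cells[class_col])]
    extra = sorted(set(cells[class_col]) - set(CLASS_ORDER))
    classes += extra
    if len(groups) < 2:
        raise InputError(f"need >= 2 groups in '{group_by}', got {groups}")
    if len(classes) < 2:
        raise InputError(f"need >= 2 classes present, got {classes}")
    table = pd.crosstab(cells[group_by], cells[class_col]).reindex(
        index=groups, columns=classes, fill_value=0
    )
    p = fisher_exact_rxc(table.to_numpy(), max_total=max_total)
    return table, p


@dataclass
class PairedComparison:
    """Paired per-cell results across two conditions (contexts or behaviors)."""

    table: pd.DataFrame
    counts: dict

    def __repr__(self) -> str:  # compact, counts carry the story
        return f"PairedComparison(n_included={self.counts.get('n_included')}, counts={self.counts})"


def _pair(results_a: pd.DataFrame, results_b: pd.DataFrame, suffixes) -> pd.DataFrame:
    cols = ["cell_id", "peak", "cell_class"]
    for df, name in ((results_a, "A"), (results_b, "B")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise InputError(f"results {name} lack columns {missing}")
    merged = results_a[cols].merge(
        results_b[cols], on="cell_id", how="inner", suffixes=suffixes
    )
    if merged.empty:
        raise InputError("no shared cell ids between the two result sets")
    return merged


def cross_context_compare(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
) -> PairedComparison:
    """Pair per-cell stop results across two behavioral contexts.

    Only cells significant (excited or inhibited) in at least one context
    enter the paired table; the counts report how consistent class labels
    are across contexts.
    """
    merged = _pair(results_a, results_b, ("_a", "_b"))
    sig = (merged["cell_class_a"] != CLASS_UNCORRELATED) | (
        merged["cell_class_b"] != CLASS_UNCORRELATED
    )
    inc = merged[sig].reset_index(drop=True)
    counts = {
        "n_shared": int(len(merged)),
        "n_included": int(len(inc)),
        "excited_both": int(
            ((inc["cell_class_a"] == CLASS_EXCITED) & (inc["cell_class_b"] == CLASS_EXCITED)).sum()
        ),
        "excited_either": int(
            ((inc["cell_class_a"] == CLASS_EXCITED) | (inc["cell_class_b"] == CLASS_EXCITED)).sum()
        ),
        "inhibited_both": int(
            ((inc["cell_class_a"] == CLASS_INHIBITED) & (inc["cell_class_b"] == CLASS_INHIBITED)).sum()
        ),
        "inhibited_either": int(
            ((inc["cell_class_a"] == CLASS_INHIBITED) | (inc["cell_class_b"] == CLASS_INHIBITED)).sum()
        ),
        "consistent_both": int((inc["cell_class_a"] == inc["cell_class_b"]).sum()),
    }
    return PairedComparison(table=inc, counts=counts)


def start_stop_pairing(
    stop_results: pd.DataFrame,
    start_results: pd.DataFrame,
) -> PairedComparison:
    """Pair each cell's stop response with its start response.

    Cells significant for at least one behavior are included; among cells
    significant for both, responses with opposite modulation signs
    (excited at one behavior, inhibited at the other) are counted
    separately from same-sign pairs.
    """
    merged = _pair(stop_results, start_results, ("_stop", "_start"))
    sig_stop = merged["cell_class_stop"] != CLASS_UNCORRELATED
    sig_start = merged["cell_class_start"] != CLASS_UNCORRELATED
    inc = merged[sig_stop | sig_start].reset_index(drop=True)
    if inc.empty:
        both = inc
    else:
        both = inc[
            (inc["cell_class_stop"] != CLASS_UNCORRELATED)
            & (inc["cell_class_start"] != CLASS_UNCORRELATED)
        ]
    opposite = int((both.get("cell_class_stop") != both.get("cell_class_start")).sum()) if len(both) else 0
    counts = {
        "n_shared": int(len(merged)),
        "n_included": int(len(inc)),
        "n_both_significant": int(len(both)),
        "opposite_sign": opposite,
        "same_sign": int(len(both)) - opposite,
    }
    return PairedComparison(table=inc, counts=counts)
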