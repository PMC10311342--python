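"""Tabular per-clade PD statistics.

Builds one row per (clade, subset size) pair — clades in post-order, sizes
ascending — carrying min, max, mean, and variance of PD, all computed exactly
and rendered to a configurable number of significant digits only at output
time.
"""

from __future__ import annotations

from decimal import Decimal, localcontext
from fractions import Fraction

import pandas as pd

from .minmax import backtrack_set, min_max_pd_tables
from .moments import moment_tables
from .tree import PhyloTree, clade_index

__all__ = ["clade_pd_stats", "render_stats", "render_value", "STAT_NAMES"]

STAT_NAMES = ("min", "max", "avg", "var")

_BASE_COLUMNS = [
    "clade_id",
    "clade_label",
    "clade_size",
    "leafset_digest",
    "k",
    "min_pd",
    "max_pd",
    "avg_pd",
    "var_pd",
]


def render_value(x: Fraction, precision: int = 6, exact: bool = False) -> str:
    """Render an exact rational for output.

    ``exact=True`` keeps the rational form (``22/3``); otherwise the value is
    rounded (half-even) to ``precision`` significant digits.
    """
    if exact:
        return str(x.numerator) if x.denominator == 1 else f"{x.numerator}/{x.denominator}"
    with localcontext() as ctx:
        ctx.prec = precision
        d = Decimal(x.numerator) / Decimal(x.denominator)
    return str(d)


def clade_pd_stats(
    tree: PhyloTree,
    k: int | None = None,
    stats=STAT_NAMES,
    clades="all",
    report_sets: bool = False,
) -> pd.DataFrame:
    """Exact PD statistics for each selected clade and every size up to k.

    Parameters
    ----------
    tree : PhyloTree
        Full binary tree.
    k : int, optional
        Maximum subset size (default n, the worst case).
    stats : iterable of {"min", "max", "avg", "var"}
        Statistics to include; omitted ones yield empty columns.
    clades : "all", "root", or a clade reference
        Which clades get rows.
    report_sets : bool
        Add ``min_set``/``max_set`` columns with backtracked optimal subsets
        (semicolon-joined labels).

    Returns
    -------
    pandas.DataFrame
        Numeric cells hold exact :class:`~fractions.Fraction` values; use
        :func:`render_stats` to format for output.
    """
    n = tree.n_leaves
    if k is None:
        k = n
    stats = tuple(stats)
    unknown = set(stats) - set(STAT_NAMES)
    if unknown:
        raise ValueError(f"unknown statistics {sorted(unknown)}")

    need_minmax = bool({"min", "max"} & set(stats)) or report_sets
    need_moments = bool({"avg", "var"} & set(stats))
    mm = min_max_pd_tables(tree, k) if need_minmax else None
    mo = moment_tables(tree, k) if need_moments else None

    if clades == "all":
        selected = list(tree.postorder())
    elif clades == "root":
        selected = [tree.root]
    else:
        selected = [tree.find_clade(clades)]

    index = {c.clade_id: c for c in clade_index(tree)}
    rows = []
    for v in selected:
        info = index[v]
        for ki in range(1, min(k, info.size) + 1):
            row = {
                "clade_id": info.clade_id,
                "clade_label": info.label,
                "clade_size": info.size,
                "leafset_digest": info.leafset_digest,
                "k": ki,
                "min_pd": mm.min_pd(v, ki) if mm and "min" in stats else None,
                "max_pd": mm.max_pd(v, ki) if mm and "max" in stats else None,
                "avg_pd": mo.avg_pd(v, ki) if mo and "avg" in stats else None,
                "var_pd": mo.var_pd(v, ki) if mo and "var" in stats else None,
            }
            if report_sets:
                row["min_set"] = ";".join(backtrack_set(tree, mm, v, ki, "min"))
                row["max_set"] = ";".join(backtrack_set(tree, mm, v, ki, "max"))
            rows.append(row)
    columns = _BASE_COLUMNS + (["min_set", "max_set"] if report_sets else [])
    return pd.DataFrame(rows, columns=columns)


def render_stats(
    df: pd.DataFrame, precision: int = 6, exact: bool = False
) -> pd.DataFrame:
    """Format the exact-rational cells of a stats table as strings."""
    out = df.copy()
    for col in ("min_pd", "max_pd", "avg_pd", "var_pd"):
        out[col] = [
            "" if x is None else render_value(x, precision, exact)
            for x in df[col]
        ]
    return out
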