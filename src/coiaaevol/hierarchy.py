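"""Taxonomy-stratified divergence summaries.

Three hierarchical distance metrics per order, all built from the
BIN-level pairwise distance matrix:

* **Order Distance** — mean distance of BINs to the outgroup, averaged
  first within each family and then (unweighted) across families.
* **Family Distance** — for each family, the mean distance between its
  BINs and the BINs of every *other* family in the same order; the
  order-level value is the unweighted mean across families.
* **BIN Distance** — for each family with two or more BINs, the mean
  distance among its within-family BIN pairs.

The **Overall Distance** of an order is the arithmetic mean of the three
(missing if any component is undefined, e.g. single-family orders).
Records without a family name are excluded from family averaging but
their outgroup distances are still reported under an empty family label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

TAXONOMY_COLUMNS = ("order", "family", "genus")


@dataclass
class HierarchySummary:
    order: str
    n_bins: int
    n_families: int
    order_distance: float
    family_distance: float
    bin_distance: float
    overall_distance: float
    se_order: float
    se_family: float
    se_bin: float


def _check_taxonomy(taxonomy: pd.DataFrame) -> None:
    missing = set(TAXONOMY_COLUMNS) - set(taxonomy.columns)
    if missing:
        raise ValueError(f"taxonomy missing columns: {sorted(missing)}")


def standard_errors(values) -> float:
    """Sample SD / sqrt(n); NaN for n < 2."""
    arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(arr.std(ddof=1) / math.sqrt(arr.size))


def order_distance(dm: DistanceMatrix, taxonomy: pd.DataFrame,
                   outgroup_id: str) -> tuple[pd.Series, pd.Series]:
    """Two-stage mean distance to the outgroup.

    Returns ``(per_order, per_family)`` where ``per_family`` is indexed
    by (order, family) and includes empty-family groups; ``per_order``
    averages only named families and is NaN for orders with none.
    """
    _check_taxonomy(taxonomy)
    if outgroup_id not in dm.ids:
        raise ValueError(f"outgroup {outgroup_id!r} not in distance matrix")
    ids = [i for i in taxonomy.index if i != outgroup_id and i in set(dm.ids)]
    d_out = pd.Series({i: dm.get(i, outgroup_id) for i in ids})
    tax = taxonomy.loc[ids]
    fam_means = d_out.groupby([tax["order"], tax["family"]]).mean()
    named = fam_means[fam_means.index.get_level_values("family") != ""]
    per_order = named.groupby(level="order").mean()
    per_order = per_order.reindex(sorted(tax["order"].unique()))
    return per_order, fam_means


def family_distance(dm: DistanceMatrix, taxonomy: pd.DataFrame,
                    outgroup_id: str | None = None
                    ) -> tuple[pd.Series, pd.Series]:
    """Among-family divergence within each order.

    Per family: the mean distance over all (BIN in family) x (BIN in any
    other named family of the same order) pairs.  Orders with fewer than
    two named families get NaN.  Returns ``(per_order, per_family)``.
    """
    _check_taxonomy(taxonomy)
    df = dm.to_dataframe()
    fam_vals: dict[tuple[str, str], float] = {}
    order_vals: dict[str, float] = {}
    tax = taxonomy[taxonomy.index != outgroup_id] if outgroup_id else taxonomy
    tax = tax[tax.index.isin(df.index)]
    for order, sub in tax.groupby("order"):
        fams = {f: list(g.index) for f, g in sub.groupby("family") if f != ""}
        if len(fams) < 2:
            order_vals[order] = float("nan")
            continue
        vals = []
        for f, members in fams.items():
            others = [i for g, mem in fams.items() if g != f for i in mem]
            block = df.loc[members, others].to_numpy(dtype=float)
            fam_vals[(order, f)] = float(np.nanmean(block))
            vals.append(fam_vals[(order, f)])
        order_vals[order] = float(np.nanmean(vals))
    per_family = pd.Series(fam_vals).sort_index() if fam_vals else pd.Series(dtype=float)
    return pd.Series(order_vals).sort_index(), per_family


def bin_distance(dm: DistanceMatrix, taxonomy: pd.DataFrame,
                 outgroup_id: str | None = None
                 ) -> tuple[pd.Series, pd.Series]:
    """Within-family divergence among BINs.

    Per family with >= 2 BINs: mean over all within-family pairs;
    single-BIN families are NaN.  The order value averages the defined
    family values.  Returns ``(per_order, per_family)``.
    """
    _check_taxonomy(taxonomy)
    df = dm.to_dataframe()
    fam_vals: dict[tuple[str, str], float] = {}
    tax = taxonomy[taxonomy.index != outgroup_id] if outgroup_id else taxonomy
    tax = tax[tax.index.isin(df.index)]
    for (order, fam), grp in tax.groupby(["order", "family"]):
        if fam == "":
            continue
        members = list(grp.index)
        if len(members) < 2:
            fam_vals[(order, fam)] = float("nan")
            continue
        block = df.loc[members, members].to_numpy(dtype=float)
        iu = np.triu_indices(len(members), k=1)
        fam_vals[(order, fam)] = float(np.nanmean(block[iu]))
    per_family = pd.Series(fam_vals).sort_index() if fam_vals else pd.Series(dtype=float)
    if len(per_family):
        per_order = per_family.groupby(level=0).mean()
    else:
        per_order = pd.Series(dtype=float)
    return per_order, per_family


def overall_distance(order_d: float, family_d: float, bin_d: float,
                     decimals: int | None = None) -> float:
    """Mean of the three components; NaN if any is missing.

    ``decimals`` applies round-half-even rounding for reporting.
    """
    if any(v is None or math.isnan(v) for v in (order_d, family_d, bin_d)):
        return float("nan")
    value = (order_d + family_d + bin_d) / 3.0
    return round(value, decimals) if decimals is not None else value


def elevate_rank(taxonomy: pd.DataFrame, order: str) -> pd.DataFrame:
    """Raise every genus of ``order`` to family rank.

    BINs with an empty genus keep their family; other orders are
    untouched.  Returns a new taxonomy table.
    """
    _check_taxonomy(taxonomy)
    if order not in set(taxonomy["order"]):
        raise ValueError(f"order {order!r} not present in taxonomy")
    out = taxonomy.copy()
    mask = (out["order"] == order) & (out["genus"] != "")
    out.loc[mask, "family"] = out.loc[mask, "genus"]
    return out


def summarize(dm: DistanceMatrix, taxonomy: pd.DataFrame,
              outgroup_id: str) -> pd.DataFrame:
    """Per-order summary table: BIN/family counts, the three distances
    with standard errors, and the Overall Distance."""
    _check_taxonomy(taxonomy)
    od, od_fam = order_distance(dm, taxonomy, outgroup_id)
    fd, fd_fam = family_distance(dm, taxonomy, outgroup_id)
    bd, bd_fam = bin_distance(dm, taxonomy, outgroup_id)
    tax = taxonomy[taxonomy.index != outgroup_id]
    rows = []
    for order in sorted(tax["order"].unique()):
        sub = tax[tax["order"] == order]
        n_bins = len(sub)
        named = sub[sub["family"] != ""]
        n_families = named["family"].nunique()
        o = float(od.get(order, float("nan")))
        f = float(fd.get(order, float("nan")))
        b = float(bd.get(order, float("nan")))
        fam_o = od_fam.loc[order] if order in od_fam.index.get_level_values(0) else pd.Series(dtype=float)
        fam_o = fam_o[fam_o.index != ""] if len(fam_o) else fam_o
        fam_f = fd_fam.loc[order] if len(fd_fam) and order in fd_fam.index.get_level_values(0) else pd.Series(dtype=float)
        fam_b = bd_fam.loc[order] if len(bd_fam) and order in bd_fam.index.get_level_values(0) else pd.Series(dtype=float)
        rows.append(HierarchySummary(
            order=order, n_bins=n_bins, n_families=n_families,
            order_distance=o, family_distance=f, bin_distance=b,
            overall_distance=overall_distance(o, f, b),
            se_order=standard_errors(fam_o),
            se_family=standard_errors(fam_f),
            se_bin=standard_errors(fam_b.dropna()),
        ))
    return pd.DataFrame([vars(r) for r in rows]).set_index("order")


def per_family_table(dm: DistanceMatrix, taxonomy: pd.DataFrame,
                     outgroup_id: str) -> pd.DataFrame:
    """Family-level table: outgroup mean, family and BIN distances."""
    _, od_fam = order_distance(dm, taxonomy, outgroup_id)
    _, fd_fam = family_distance(dm, taxonomy, outgroup_id)
    _, bd_fam = bin_distance(dm, taxonomy, outgroup_id)
    tax = taxonomy[taxonomy.index != outgroup_id]
    counts = tax.groupby(["order", "family"]).size()
    df = pd.DataFrame({
        "n_bins": counts,
        "outgroup_mean": od_fam,
        "family_distance": fd_fam,
        "bin_distance": bd_fam,
    })
    df.index.names = ["order", "family"]
    return df.sort_index()


def write_summary_tsv(summary: pd.DataFrame, path, decimals: int = 3) -> None:
    out = summary.copy()
    num_cols = [c for c in out.columns if c.startswith(("order_", "family_",
                                                       "bin_", "overall_", "se_"))]
    out[num_cols] = out[num_cols].map(
        lambda v: round(v, decimals) if not math.isnan(v) else v)
    out.to_csv(path, sep="\t", na_rep="")
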