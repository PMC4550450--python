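"""Indel detection against the consensus frame and parsimony origin counting.

An indel event is keyed by (kind, start site, length) in 1-based
consensus coordinates; deletions at neighbouring sites are distinct
events.  Validation mirrors curated-barcode practice: an event supported
by a single unvouchered (mined) record is discarded, while events seen
in several records, or in a single voucher-backed record, are retained.

Independent origins are counted on a taxonomy-derived guide tree: each
event becomes a binary presence/absence character on the BIN leaves and
the minimum number of 0->1 gains is found by a parsimony DP (Fitch-style
for a binary character, with ties resolved toward fewer gains and the
root fixed at absence).  Polytomies from unresolved taxonomy make this a
lower bound — "at least" so many origins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import dendropy
import pandas as pd

from .alignment import AlignedProtein

_INF = 10 ** 9


@dataclass
class IndelEvent:
    kind: str                 # 'insertion' | 'deletion'
    start_site: int           # 1-based consensus site (insertions: after site)
    length: int
    member_records: frozenset[str]
    families: frozenset[str] = frozenset()
    region: str = "unknown"
    origins: int | None = None

    def __post_init__(self):
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")

    @property
    def support(self) -> int:
        return len(self.member_records)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.kind, self.start_site, self.length)

    @property
    def end_site(self) -> int:
        """Last consensus site of a deletion (inclusive)."""
        return self.start_site + self.length - 1


def detect_indels(rows: list[AlignedProtein],
                  include_terminal: bool = False) -> list[IndelEvent]:
    """Find gap runs (deletions) and insertion columns per row and merge
    identical (kind, site, length) events across rows.

    Terminal gap runs are treated as missing data (incomplete
    sequences), not deletions, unless ``include_terminal`` is set.
    """
    members: dict[tuple[str, int, int], set[str]] = {}
    for row in rows:
        cols = row.columns
        n = len(cols)
        first = next((i for i, c in enumerate(cols) if c != "-"), None)
        if first is None:
            continue
        last = n - 1
        while cols[last] == "-":
            last -= 1
        i = 0 if include_terminal else first
        stop = n if include_terminal else last + 1
        while i < stop:
            if cols[i] == "-":
                j = i
                while j < stop and cols[j] == "-":
                    j += 1
                key = ("deletion", i + 1, j - i)
                members.setdefault(key, set()).add(row.record_id)
                i = j
            else:
                i += 1
        for site, residues in row.insertions:
            key = ("insertion", site, len(residues))
            members.setdefault(key, set()).add(row.record_id)
    return [IndelEvent(kind, site, length, frozenset(recs))
            for (kind, site, length), recs in sorted(members.items())]


def validate_indels(events: list[IndelEvent], records: dict,
                    min_support: int = 2) -> list[IndelEvent]:
    """Apply the support rules and attach family sets.

    ``records`` maps record_id to any object with ``source`` and
    ``family`` attributes.  An event is kept if it has at least
    ``min_support`` members spanning either two records of one family or
    two families — or if its sole member is voucher-backed.
    """
    kept = []
    for ev in events:
        fams = frozenset(records[r].family for r in ev.member_records
                         if r in records)
        by_family: dict[str, int] = {}
        for r in ev.member_records:
            if r in records:
                f = records[r].family
                by_family[f] = by_family.get(f, 0) + 1
        spans = len(by_family) >= 2 or any(c >= 2 for c in by_family.values())
        if ev.support >= min_support and spans:
            kept.append(replace(ev, families=fams))
        elif ev.support == 1:
            (sole,) = ev.member_records
            if sole in records and records[sole].source == "voucher":
                kept.append(replace(ev, families=fams))
    return kept


def classify_region(event: IndelEvent,
                    region_map: list[tuple[str, int, int]]) -> IndelEvent:
    """Label an event by the (1-based, inclusive) interval containing its
    start site; 'unknown' when uncovered."""
    intervals = sorted(region_map, key=lambda t: t[1])
    for (_, s1, e1), (_, s2, _) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise ValueError("region map intervals overlap")
    for label, start, end in intervals:
        if start <= event.start_site <= end:
            return replace(event, region=label)
    return replace(event, region="unknown")


def read_region_map(path: Path | str) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "start": int, "end": int})
    return [(r.label, int(r.start), int(r.end)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# guide tree

def build_guide_tree(taxonomy: pd.DataFrame, backbone_newick: str) -> dendropy.Tree:
    """Expand an order-level backbone into a BIN-level guide tree.

    ``taxonomy`` is indexed by BIN id with order/family/genus columns;
    backbone leaves are order names.  Each matching order leaf becomes a
    nested (family (genus (BINs))) polytomy; backbone orders without
    data are pruned.  Orders present in the data but absent from the
    backbone are an error.
    """
    tree = dendropy.Tree.get(data=backbone_newick, schema="newick")
    tree.is_rooted = True
    backbone_orders = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    data_orders = set(taxonomy["order"].unique())
    missing = sorted(data_orders - backbone_orders)
    if missing:
        raise ValueError(f"orders missing from backbone: {missing}")

    taxa = tree.taxon_namespace
    for leaf in list(tree.leaf_node_iter()):
        order = leaf.taxon.label
        if order not in data_orders:
            continue
        leaf.taxon = None
        sub = taxonomy[taxonomy["order"] == order]
        for family, fam_grp in sub.groupby("family"):
            fam_node = leaf.new_child()
            for genus, gen_grp in fam_grp.groupby("genus"):
                gen_node = fam_node.new_child()
                for bin_id in gen_grp.index:
                    child = gen_node.new_child()
                    child.taxon = taxa.new_taxon(label=str(bin_id))
    # prune backbone orders that received no BINs
    for leaf in list(tree.leaf_node_iter()):
        if leaf.taxon is not None and leaf.taxon.label in backbone_orders \
                and leaf.taxon.label not in data_orders:
            tree.prune_subtree(leaf, suppress_unifurcations=False)
    return tree


def _min_changes_and_gains(tree: dendropy.Tree, present: set[str]
                           ) -> tuple[int, int]:
    """Lexicographic DP: minimal (total changes, gains) with root state 0."""
    cost: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = 1 if node.taxon.label in present else 0
            cost[node] = {s: ((0, 0) if s == state else (_INF, _INF))
                          for s in (0, 1)}
        else:
            node_cost = {}
            for s in (0, 1):
                ch, g = 0, 0
                for child in node.child_nodes():
                    best = min(
                        (cost[child][sc][0] + (1 if sc != s else 0),
                         cost[child][sc][1] + (1 if (s == 0 and sc == 1) else 0))
                        for sc in (0, 1))
                    ch += best[0]
                    g += best[1]
                node_cost[s] = (ch, g)
            cost[node] = node_cost
    return cost[tree.seed_node][0]


def count_origins(events: list[IndelEvent], tree: dendropy.Tree,
                  leaf_of: dict[str, str]) -> tuple[list[IndelEvent], int]:
    """Minimal gains per event on the guide tree; returns annotated events
    and the total across distinct events.

    ``leaf_of`` maps member record ids to BIN leaf labels.
    """
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    annotated = []
    total = 0
    for ev in events:
        present = set()
        for r in ev.member_records:
            leaf = leaf_of.get(r, r)
            if leaf not in leaf_labels:
                raise ValueError(f"record {r!r} maps to no guide-tree leaf")
            present.add(leaf)
        _, gains = _min_changes_and_gains(tree, present)
        annotated.append(replace(ev, origins=gains))
        total += gains
    return annotated, total


def write_indel_report(events: list[IndelEvent], path: Path | str) -> None:
    rows = [(e.kind, e.start_site, e.length, e.support,
             ";".join(sorted(e.families)), e.region,
             e.origins if e.origins is not None else "")
            for e in sorted(events, key=lambda e: e.key)]
    pd.DataFrame(rows, columns=["kind", "start_site", "length", "support",
                                "families", "region", "origins"]
                 ).to_csv(path, sep="\t", index=False)
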