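"""Synthetic BOLD-like barcode datasets with known truth.

The generator emulates the structure of a curated COI barcode dataset:
a multi-order taxonomy with nested families, genera and BINs; 219-codon
reading frames evolved under the Dayhoff CTMC along a hierarchical tree;
per-order substitution-rate multipliers (optionally tied to generation
time); occasional amino-acid deletions; back-translated nucleotides
under the invertebrate mitochondrial code; and corruption in the form of
NUMT-like frameshifted duplicates and ambiguous base calls.

Within one order every branch is scaled by that order's rate
multiplier, so within-order pairwise distances are exactly proportional
to the multiplier and BIN-to-outgroup distances increase monotonically
with it.  Deletion sites are resampled when the flanking residues would
make the gap placement ambiguous, and a two-residue window on each
flank is held fixed in the descendant clade, keeping injected events
identifiable; the truth bundle also carries the exact root-frame
alignment of every leaf, from which registry coordinates are always
recoverable.  One seeded RNG stream drives global draws and one
sub-stream per order keeps outputs stable under edits elsewhere in the
configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .dayhoff import AMINO_ACIDS, SubstitutionModel, load_dayhoff_model
from .io_selection import INVERTEBRATE_MITO_CODE, SequenceRecord

N_SITES = 219

OUTGROUP_ORDER = "Xiphosurida"
OUTGROUP_BIN = "BIN_OUTGROUP"
OUTGROUP_RECORD = "REC_OUTGROUP"


@dataclass(frozen=True)
class OrderSpec:
    """Simulation parameters for one order."""

    name: str
    n_families: int
    bins_per_family: tuple[int, int] = (2, 4)
    rate_multiplier: float = 1.0
    generation_time_days: float | None = None
    indel_rate: float = 0.0  # deletions per site per unit branch length


@dataclass(frozen=True)
class SimConfig:
    seed: int
    orders: tuple[OrderSpec, ...]
    tree_height: float = 0.15      # expected subs/site, root to ingroup tips
    numt_fraction: float = 0.0
    ambiguous_base_rate: float = 0.0
    voucher_fraction: float = 2 / 3
    n_sites: int = N_SITES

    def validate(self) -> None:
        if not self.orders:
            raise ValueError("at least one order required")
        names = [o.name for o in self.orders]
        if len(set(names)) != len(names):
            raise ValueError("duplicate order names")
        for o in self.orders:
            if o.rate_multiplier <= 0:
                raise ValueError(f"{o.name}: rate_multiplier must be > 0")
            if o.n_families < 1:
                raise ValueError(f"{o.name}: n_families must be >= 1")
            lo, hi = o.bins_per_family
            if not (1 <= lo <= hi):
                raise ValueError(f"{o.name}: bad bins_per_family {o.bins_per_family}")
            if o.indel_rate < 0:
                raise ValueError(f"{o.name}: indel_rate must be >= 0")
        for name, frac in (("numt_fraction", self.numt_fraction),
                           ("ambiguous_base_rate", self.ambiguous_base_rate),
                           ("voucher_fraction", self.voucher_fraction)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.tree_height <= 0:
            raise ValueError("tree_height must be > 0")


@dataclass
class InjectedIndel:
    order: str
    kind: str
    start_site: int  # 1-based, consensus (root) frame
    length: int
    branch: str
    bins: list[str] = field(default_factory=list)


@dataclass
class TruthBundle:
    tree: dendropy.Tree
    newick: str
    multipliers: dict[str, float]
    generation_times: dict[str, float | None]
    registry: list[InjectedIndel]
    true_distances: pd.DataFrame
    root_protein: str
    leaf_proteins: dict[str, str]
    leaf_alignments: dict[str, str]  # root-frame rows, '-' at deleted sites
    bins_by_order: dict[str, list[str]]


@dataclass
class SimResult:
    config: SimConfig
    records: list[SequenceRecord]
    truth: TruthBundle
    backbone_newick: str


def _evolve(protein: np.ndarray, t: float, model: SubstitutionModel,
            rng: np.random.Generator,
            frozen: set[int] | None = None) -> np.ndarray:
    if t <= 0:
        return protein.copy()
    P = model.transition_matrix(t)
    probs = P[protein]
    u = rng.random(protein.size)
    child = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
    if frozen:
        idx = np.fromiter(frozen, dtype=int)
        child[idx] = protein[idx]
    return child


def _unambiguous(protein: np.ndarray, s: int, L: int) -> bool:
    """True when deleting 0-based sites s..s+L-1 leaves no room for the
    aligner to slide the gap (flanking residues differ)."""
    n = protein.size
    left_ok = s == 0 or protein[s - 1] != protein[s + L - 1]
    right_ok = s + L >= n or protein[s] != protein[s + L]
    return left_ok and right_ok


def _min_gap_ok(dels: set[int], s: int, L: int, min_gap: int = 3) -> bool:
    return all(not (s - min_gap <= d <= s + L - 1 + min_gap) for d in dels)


_CODON_CHOICES: dict[str, list[str]] | None = None


def _codon_choices() -> dict[str, list[str]]:
    global _CODON_CHOICES
    if _CODON_CHOICES is None:
        fwd = CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_CODE].forward_table
        table: dict[str, list[str]] = {}
        for codon, aa in sorted(fwd.items()):
            table.setdefault(aa, []).append(codon)
        _CODON_CHOICES = table
    return _CODON_CHOICES


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    table = _codon_choices()
    out = []
    for aa in protein:
        codons = table[aa]
        out.append(codons[int(rng.integers(len(codons)))])
    return "".join(out)


def simulate_dataset(config: SimConfig,
                     out_dir: Path | str | None = None) -> SimResult:
    """Simulate a dataset; optionally write FASTA/metadata/backbone/truth.

    Returns a :class:`SimResult` whose truth bundle holds the true tree,
    patristic distances, rate multipliers and the injected indel
    registry (all recoverable from the emitted alignment).
    """
    config.validate()
    model = load_dayhoff_model()
    n_sites = config.n_sites
    H = config.tree_height

    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(len(config.orders) + 1)
    grng = np.random.default_rng(streams[0])

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    root_protein = grng.choice(20, size=n_sites, p=model.equilibrium_freqs)

    registry: list[InjectedIndel] = []
    leaf_info: list[dict] = []  # one per emitted ingroup leaf

    # outgroup: a single long branch from the root at rate 1
    og = root.new_child(edge_length=H)
    og.taxon = taxa.new_taxon(label=OUTGROUP_BIN)
    og_protein = _evolve(root_protein, H, model, grng)

    order_h = 0.6 * H
    for k, spec in enumerate(config.orders):
        rng = np.random.default_rng(streams[k + 1])
        m = spec.rate_multiplier
        order_node = root.new_child(edge_length=(H - order_h) * m)
        state = {"protein": _evolve(root_protein, (H - order_h) * m, model, rng),
                 "dels": set(), "frozen": set()}
        _inject_indels(state, spec, (H - order_h) * m, n_sites, rng,
                       registry, root_protein, f"{spec.name}/stem")
        _attach_registry_nodes(registry, f"{spec.name}/stem", order_node)
        order_state = state

        for j in range(spec.n_families):
            family = f"{spec.name}_F{j + 1:02d}"
            fam_h = rng.uniform(0.25, 0.55) * H
            blen = (order_h - fam_h) * m
            fam_node = order_node.new_child(edge_length=blen)
            fam_state = {"protein": _evolve(order_state["protein"], blen, model,
                                            rng, order_state["frozen"]),
                         "dels": set(order_state["dels"]),
                         "frozen": set(order_state["frozen"])}
            _inject_indels(fam_state, spec, blen, n_sites, rng, registry,
                           root_protein, f"{family}")
            _attach_registry_nodes(registry, f"{family}", fam_node)

            lo, hi = spec.bins_per_family
            n_bins = int(rng.integers(lo, hi + 1))
            n_genera = 1 + (n_bins - 1) // 3
            assignments = [b % n_genera for b in range(n_bins)]
            for g in range(n_genera):
                genus = f"{family}_G{g + 1}"
                gen_h = fam_h * rng.uniform(0.3, 0.6)
                blen = (fam_h - gen_h) * m
                gen_node = fam_node.new_child(edge_length=blen)
                gen_state = {"protein": _evolve(fam_state["protein"], blen, model,
                                                rng, fam_state["frozen"]),
                             "dels": set(fam_state["dels"]),
                             "frozen": set(fam_state["frozen"])}
                _inject_indels(gen_state, spec, blen, n_sites, rng, registry,
                               root_protein, genus)
                _attach_registry_nodes(registry, genus, gen_node)
                for b, ga in enumerate(assignments):
                    if ga != g:
                        continue
                    bin_id = f"BIN_{spec.name}_{j + 1:02d}_{b + 1:02d}"
                    blen = gen_h * m
                    leaf = gen_node.new_child(edge_length=blen)
                    leaf.taxon = taxa.new_taxon(label=bin_id)
                    leaf_state = {"protein": _evolve(gen_state["protein"], blen,
                                                     model, rng,
                                                     gen_state["frozen"]),
                                  "dels": set(gen_state["dels"]),
                                  "frozen": set(gen_state["frozen"])}
                    _inject_indels(leaf_state, spec, blen, n_sites, rng,
                                   registry, root_protein, bin_id)
                    _attach_registry_nodes(registry, bin_id, leaf)
                    leaf_info.append({
                        "bin_id": bin_id, "order": spec.name, "family": family,
                        "genus": genus, "node": leaf, "state": leaf_state,
                        "rng": rng,
                    })

    # resolve registry membership: every leaf below the event's branch node
    node_leaves: dict[int, list[str]] = {}
    for entry in registry:
        node = entry._node  # attached below
        key = id(node)
        if key not in node_leaves:
            node_leaves[key] = sorted(
                l.taxon.label for l in node.leaf_iter() if l.taxon is not None)
        entry.bins = node_leaves[key]
        del entry._node

    # emit sequences
    records: list[SequenceRecord] = []
    leaf_proteins: dict[str, str] = {}
    leaf_alignments: dict[str, str] = {}
    og_prot_str = "".join(AMINO_ACIDS[i] for i in og_protein)
    leaf_proteins[OUTGROUP_BIN] = og_prot_str
    leaf_alignments[OUTGROUP_BIN] = og_prot_str
    records.append(SequenceRecord(
        record_id=OUTGROUP_RECORD, bin_id=OUTGROUP_BIN, order=OUTGROUP_ORDER,
        family="Limulidae", genus="Limulus",
        nt_seq=_back_translate(og_prot_str, grng), source="voucher"))

    for info in leaf_info:
        state, rng = info["state"], info["rng"]
        prot = "".join(AMINO_ACIDS[int(a)] for i, a in enumerate(state["protein"])
                       if i not in state["dels"])
        leaf_proteins[info["bin_id"]] = prot
        leaf_alignments[info["bin_id"]] = "".join(
            "-" if i in state["dels"] else AMINO_ACIDS[int(a)]
            for i, a in enumerate(state["protein"]))
        nt = _back_translate(prot, rng)
        if config.ambiguous_base_rate > 0:
            mask = rng.random(len(nt)) < config.ambiguous_base_rate
            nt = "".join("N" if mask[i] else c for i, c in enumerate(nt))
        source = "voucher" if rng.random() < config.voucher_fraction else "mined"
        records.append(SequenceRecord(
            record_id=f"REC_{info['bin_id']}", bin_id=info["bin_id"],
            order=info["order"], family=info["family"], genus=info["genus"],
            nt_seq=nt, source=source))

    # NUMT-like contaminants: frameshifted duplicates of random BINs
    n_numt = int(round(config.numt_fraction * len(leaf_info)))
    if n_numt > 0:
        pool = [r for r in records if r.record_id != OUTGROUP_RECORD]
        picks = grng.choice(len(pool), size=n_numt, replace=False)
        for idx in sorted(picks):
            src = pool[int(idx)]
            pos = int(grng.integers(len(src.nt_seq)))
            base = "ACGT"[int(grng.integers(4))]
            records.append(SequenceRecord(
                record_id=f"{src.record_id}_NUMT", bin_id=src.bin_id,
                order=src.order, family=src.family, genus=src.genus,
                nt_seq=src.nt_seq[:pos] + base + src.nt_seq[pos:],
                source="mined"))

    newick = tree.as_string(schema="newick").strip()
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in taxa)
    dist = pd.DataFrame(0.0, index=labels, columns=labels)
    taxon_of = {t.label: t for t in taxa}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = pdm.patristic_distance(taxon_of[a], taxon_of[b])
            dist.loc[a, b] = dist.loc[b, a] = d

    truth = TruthBundle(
        tree=tree, newick=newick,
        multipliers={o.name: o.rate_multiplier for o in config.orders},
        generation_times={o.name: o.generation_time_days for o in config.orders},
        registry=registry, true_distances=dist,
        root_protein="".join(AMINO_ACIDS[int(i)] for i in root_protein),
        leaf_proteins=leaf_proteins, leaf_alignments=leaf_alignments,
        bins_by_order={o.name: [i["bin_id"] for i in leaf_info
                                if i["order"] == o.name]
                       for o in config.orders},
    )
    order_names = ",".join(o.name for o in config.orders)
    backbone = f"({OUTGROUP_ORDER},({order_names}));"
    result = SimResult(config, records, truth, backbone)
    if out_dir is not None:
        write_dataset(result, Path(out_dir))
    return result


def _inject_indels(state: dict, spec: OrderSpec, branch_len: float,
                   n_sites: int, rng: np.random.Generator,
                   registry: list[InjectedIndel], root_protein: np.ndarray,
                   branch_id: str) -> None:
    if spec.indel_rate <= 0 or branch_len <= 0:
        return
    n_events = int(rng.poisson(spec.indel_rate * branch_len * n_sites))
    for _ in range(n_events):
        for _attempt in range(100):
            L = int(rng.integers(1, 6))
            s = int(rng.integers(3, n_sites - L - 3))
            if not _min_gap_ok(state["dels"], s, L):
                continue
            if not (_unambiguous(root_protein, s, L)
                    and _unambiguous(state["protein"], s, L)):
                continue
            # a two-residue window on each flank must still match the
            # ancestral frame, otherwise the optimal gap placement
            # against the consensus may shift
            flank = [i for i in (s - 2, s - 1, s + L, s + L + 1)
                     if 0 <= i < n_sites]
            if any(state["protein"][i] != root_protein[i] for i in flank):
                continue
            state["dels"].update(range(s, s + L))
            # keep the flanking residues fixed in this clade so the gap
            # placement stays identifiable at its exact coordinates
            state["frozen"].update(i for i in (s - 2, s - 1, s + L, s + L + 1)
                                   if 0 <= i < n_sites)
            entry = InjectedIndel(order=spec.name, kind="deletion",
                                  start_site=s + 1, length=L, branch=branch_id)
            entry._node = None  # filled by _attach_registry_nodes
            entry._branch_key = branch_id
            registry.append(entry)
            break


def _attach_registry_nodes(registry: list[InjectedIndel],
                                  branch_id: str, node) -> None:
    for entry in registry:
        if getattr(entry, "_branch_key", None) == branch_id and entry._node is None:
            entry._node = node


def write_dataset(result: SimResult, out_dir: Path) -> dict[str, Path]:
    """Write FASTA, metadata TSV, backbone newick and truth JSON."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "sequences.fasta",
        "metadata": out_dir / "metadata.tsv",
        "backbone": out_dir / "backbone.nwk",
        "truth": out_dir / "truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for r in result.records:
            fh.write(f">{r.record_id}\n{r.nt_seq}\n")
    pd.DataFrame(
        [(r.record_id, r.bin_id, r.order, r.family, r.genus, r.source)
         for r in result.records],
        columns=["record_id", "bin_id", "order", "family", "genus", "source"]
    ).to_csv(paths["metadata"], sep="\t", index=False)
    paths["backbone"].write_text(result.backbone_newick + "\n")
    truth = result.truth
    payload = {
        "seed": result.config.seed,
        "newick": truth.newick,
        "multipliers": truth.multipliers,
        "generation_times": truth.generation_times,
        "registry": [{k: v for k, v in dataclasses.asdict(e).items()}
                     for e in truth.registry],
        "bins_by_order": truth.bins_by_order,
        "true_distances": {f"{a}|{b}": round(truth.true_distances.loc[a, b], 6)
                           for i, a in enumerate(truth.true_distances.index)
                           for b in truth.true_distances.index[i + 1:]},
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths


# ---------------------------------------------------------------------------
# bundled reference fixture

@dataclass(frozen=True)
class FixturePaths:
    fasta: Path
    metadata: Path
    backbone: Path
    truth: Path
    expected_table1: Path
    expected_indels: Path


#: Configuration the bundled fixture was generated from (seed included).
FIXTURE_CONFIG = SimConfig(
    seed=20150826,
    orders=(
        OrderSpec("Alphida", n_families=4, bins_per_family=(2, 4),
                  rate_multiplier=1.0, generation_time_days=900.0),
        OrderSpec("Betida", n_families=3, bins_per_family=(2, 4),
                  rate_multiplier=2.0, generation_time_days=300.0,
                  indel_rate=0.008),
        OrderSpec("Gammida", n_families=3, bins_per_family=(3, 5),
                  rate_multiplier=3.0, generation_time_days=60.0,
                  indel_rate=0.008),
        OrderSpec("Deltida", n_families=2, bins_per_family=(2, 3),
                  rate_multiplier=1.5, generation_time_days=500.0),
    ),
    tree_height=0.15,
    numt_fraction=0.05,
    ambiguous_base_rate=0.001,
)


def reference_fixture() -> FixturePaths:
    """Paths of the committed mini-dataset (generated from FIXTURE_CONFIG)."""
    from importlib.resources import files
    base = files("coiaaevol") / "data" / "fixture"
    return FixturePaths(
        fasta=Path(str(base / "sequences.fasta")),
        metadata=Path(str(base / "metadata.tsv")),
        backbone=Path(str(base / "backbone.nwk")),
        truth=Path(str(base / "truth.json")),
        expected_table1=Path(str(base / "expected_table1.tsv")),
        expected_indels=Path(str(base / "expected_indels.tsv")),
    )
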