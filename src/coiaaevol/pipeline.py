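"""End-to-end orchestration: QC -> representatives -> alignment ->
distances -> hierarchy tables -> indels -> stats, with a run manifest.

Every stage writes a plain-text TSV/JSON artifact into the output
directory, and the whole run is a pure function of (inputs, config):
rerunning the same configuration reproduces the same manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass
from importlib.resources import files as _pkg_files
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment import build_reference_frame, write_alignment_fasta, \
    write_consensus_fasta
from .dayhoff import load_dayhoff_model
from .distances import distance_matrix
from .hierarchy import elevate_rank, per_family_table, summarize, \
    write_summary_tsv
from .indels import build_guide_tree, classify_region, count_origins, \
    detect_indels, read_region_map, validate_indels, write_indel_report
from .io_selection import read_records, screen_numt, select_representatives, \
    translate, write_qc_report, write_representatives
from .stats import indel_family_contrast, ols

logger = logging.getLogger("coiaaevol")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def default_backbone_path() -> Path:
    """Packaged order-level arachnid backbone topology."""
    return Path(str(_pkg_files("coiaaevol") / "data" / "arachnid_backbone.nwk"))


@dataclass
class RunConfig:
    fasta: Path
    metadata: Path
    outgroup_id: str            # record id of the outgroup sequence
    out_dir: Path
    backbone: Path | None = None
    metric: str = "dayhoff"
    min_support: int = 2
    min_codons: int = 150
    region_map: Path | None = None
    generation_times: Path | None = None  # TSV: order, mean_generation_time_days
    elevate_orders: tuple[str, ...] = ()
    gap_open: float = 10.0
    gap_extend: float = 1.0
    score_floor: float = 0.0
    decimals: int = 3
    seed: int = 0

    def as_dict(self) -> dict:
        d = {}
        for k, v in vars(self).items():
            d[k] = str(v) if isinstance(v, Path) else (
                list(v) if isinstance(v, tuple) else v)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns a summary dict (also written as
    ``manifest.json`` plus per-stage TSV/JSON artifacts)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    model = load_dayhoff_model()
    stage = "read"
    try:
        records = read_records(config.fasta, config.metadata)
        rec_by_id = {r.record_id: r for r in records}
        if config.outgroup_id not in rec_by_id:
            raise ValueError(f"outgroup id {config.outgroup_id!r} not in inputs")

        stage = "qc"
        qc = {r.record_id: screen_numt(r, min_codons=config.min_codons)
              for r in records}
        write_qc_report(qc, out / "qc_report.tsv")
        logger.info("stage=qc n=%d failed=%d elapsed=%.1fs", len(qc),
                    sum(not q.passes for q in qc.values()), time.time() - t0)

        stage = "select"
        reps = select_representatives(records, qc=qc)
        write_representatives(reps, out / "representatives.tsv")
        rep_ids = set(reps.values())
        if config.outgroup_id not in rep_ids:
            raise ValueError("outgroup record was not selected as its BIN's "
                             "representative; check its QC status")

        stage = "align"
        rep_proteins = {rid: translate(rec_by_id[rid],
                                       qc[rid].chosen_frame)
                        for rid in sorted(rep_ids)}
        consensus, rows, skipped = build_reference_frame(
            rep_proteins, model, gap_open=config.gap_open,
            gap_extend=config.gap_extend, score_floor=config.score_floor)
        for rid in skipped:
            logger.warning("unalignable record=%s", rid)
        write_alignment_fasta(rows, out / "alignment.fasta")
        write_consensus_fasta(consensus, out / "consensus.fasta")

        stage = "distances"
        dm_p = distance_matrix(rows, "p")
        dm_d = distance_matrix(rows, "dayhoff", model=model)
        dm_p.write_square_tsv(out / "dist_p.tsv")
        dm_d.write_square_tsv(out / "dist_dayhoff.tsv")
        dm = dm_d if config.metric == "dayhoff" else dm_p
        logger.info("stage=distances n=%d elapsed=%.1fs", len(dm.ids),
                    time.time() - t0)

        stage = "summarize"
        aligned_ids = {r.record_id for r in rows}
        taxonomy = pd.DataFrame(
            {"order": {rid: rec_by_id[rid].order for rid in aligned_ids},
             "family": {rid: rec_by_id[rid].family for rid in aligned_ids},
             "genus": {rid: rec_by_id[rid].genus for rid in aligned_ids},
             "bin_id": {rid: rec_by_id[rid].bin_id for rid in aligned_ids}})
        taxonomy = taxonomy.sort_index()
        table1 = summarize(dm, taxonomy, config.outgroup_id)
        write_summary_tsv(table1, out / "table1.tsv", config.decimals)
        fam_table = per_family_table(dm, taxonomy, config.outgroup_id)
        fam_table.round(6).to_csv(out / "per_family.tsv", sep="\t", na_rep="")

        stage = "elevate"
        table2 = None
        if config.elevate_orders:
            frames = []
            for order in config.elevate_orders:
                elevated = elevate_rank(taxonomy, order)
                t2 = summarize(dm, elevated, config.outgroup_id)
                frames.append(t2.loc[[order]])
            table2 = pd.concat(frames)
            write_summary_tsv(table2, out / "table2.tsv", config.decimals)

        stage = "indels"
        # support pool: QC-passing records plus QC-failing vouchers
        pool_ids = {r.record_id for r in records
                    if qc[r.record_id].passes or r.source == "voucher"}
        extra = sorted(pool_ids - aligned_ids - {config.outgroup_id})
        extra_proteins = {}
        for rid in extra:
            try:
                extra_proteins[rid] = translate(
                    rec_by_id[rid], qc[rid].chosen_frame, on_stop="mask")
            except Exception:  # pragma: no cover - defensive
                continue
        from .alignment import align_rows
        extra_rows, extra_skipped = align_rows(
            extra_proteins, consensus, model, gap_open=config.gap_open,
            gap_extend=config.gap_extend, score_floor=config.score_floor)
        pool_rows = [r for r in rows if r.record_id != config.outgroup_id] \
            + extra_rows
        events = detect_indels(pool_rows)
        events = validate_indels(events, rec_by_id,
                                 min_support=config.min_support)
        if config.region_map is not None:
            region_map = read_region_map(config.region_map)
            events = [classify_region(e, region_map) for e in events]
        backbone_path = config.backbone or default_backbone_path()
        backbone = Path(backbone_path).read_text()
        guide_taxonomy = taxonomy[taxonomy.index != config.outgroup_id] \
            .set_index("bin_id")[["order", "family", "genus"]]
        tree = build_guide_tree(guide_taxonomy, backbone)
        leaf_of = {r.record_id: r.bin_id for r in records}
        events, total_origins = count_origins(events, tree, leaf_of)
        write_indel_report(events, out / "indels.tsv")
        logger.info("stage=indels events=%d origins=%d", len(events),
                    total_origins)

        stage = "stats"
        stats_out: dict = {"n_bins": int(len(taxonomy) - 1),
                           "n_indel_events": len(events),
                           "total_indel_origins": total_origins}
        complete = table1.dropna(subset=["order_distance", "family_distance",
                                         "bin_distance"])
        if len(complete) >= 3:
            for col, key in (("family_distance", "order_vs_family"),
                             ("bin_distance", "order_vs_bin")):
                fit = ols(complete[col], complete["order_distance"])
                stats_out[key] = vars(fit)
        if config.generation_times is not None:
            gt = pd.read_csv(config.generation_times, sep="\t")
            gt = gt.set_index("order")["mean_generation_time_days"]
            joined = table1.join(gt, how="inner").dropna(
                subset=["order_distance", "mean_generation_time_days"])
            if len(joined) >= 3:
                fit = ols(joined["mean_generation_time_days"],
                          joined["order_distance"])
                stats_out["generation_time_vs_order"] = vars(fit)
        indel_families = set().union(*[e.families for e in events]) \
            if events else set()
        fam_series = fam_table["family_distance"].dropna()
        try:
            contrast = indel_family_contrast(fam_series, indel_families)
            stats_out["indel_family_contrast"] = {
                "t_statistic": contrast.t_statistic, "df": contrast.df,
                "p_value": contrast.p_value,
                "mean_with_indels": contrast.group_means[0],
                "mean_without_indels": contrast.group_means[1],
                "n_with": contrast.group_sizes[0],
                "n_without": contrast.group_sizes[1]}
        except ValueError:
            stats_out["indel_family_contrast"] = None
        (out / "stats.json").write_text(json.dumps(stats_out, indent=1))

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": config.as_dict(),
            "inputs": {"fasta": _sha256(Path(config.fasta)),
                       "metadata": _sha256(Path(config.metadata))},
            "outputs": sorted(p.name for p in out.iterdir()
                              if p.name != "manifest.json"),
            "n_records": len(records),
            "n_representatives": len(reps),
            "skipped_unalignable": skipped + extra_skipped,
        }
        manifest["hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True).encode()).hexdigest()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.info("done elapsed=%.1fs", time.time() - t0)
        return {"manifest": manifest, "table1": table1, "table2": table2,
                "events": events, "total_origins": total_origins,
                "stats": stats_out}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
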