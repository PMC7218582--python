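"""End-to-end orchestration: simulate/load → QC → denoise → gate →
decontaminate → diversity / mock evaluation, driven by a single YAML config.

Every threshold is a named config key with the workflow's default value;
the run summary JSON records all parameters, per-stage removal counts and
contaminant calls, and re-running with the same config and seed reproduces
outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import decontam as dc
from . import denoise as dn
from . import diversity as dv
from . import io
from . import mock_eval as me
from . import qc as qcmod
from . import simulate as sim

__all__ = ["PipelineError", "load_config", "run_pipeline", "DEFAULT_THRESHOLDS"]

logger = logging.getLogger("lbqc")

DEFAULT_THRESHOLDS: dict[str, Any] = {
    "min_total_reads": 5,  # spurious OTU grand-total cut
    "biomass_cutoff": 500.0,  # copies/μl, strict >
    "classifier_threshold": 0.1,
    "cut_primary": 0.99,  # complete-linkage cut heights
    "cut_secondary": 0.90,
    "n_permutations": 1000,
    "zero_alpha": 0.5,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", "top-level config must be a mapping")
    return cfg


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(sh)
    fh = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


def _acquire_inputs(cfg: Mapping, out_dir: Path):
    if "simulate" in cfg:
        params = dict(cfg["simulate"] or {})
        try:
            simcfg = sim.SimConfig(**params)
        except TypeError as e:
            raise PipelineError("simulate", f"bad simulate config: {e}") from None
        table, records, tax, truth = sim.generate_cohort(simcfg)
        io.write_count_table(table, out_dir / "counts.tsv")
        io.write_metadata(records, out_dir / "metadata.tsv")
        io.write_taxonomy(tax, out_dir / "taxonomy.tsv")
        io.write_run_summary(
            {
                "otu_origin": truth.otu_origin,
                "samples": {
                    sid: {
                        k: truth.samples.at[sid, k]
                        for k in truth.samples.columns
                    }
                    for sid in truth.samples.index
                },
            },
            out_dir / "truth.json",
        )
        logger.info(
            "simulate: %d OTUs x %d samples (seed=%d)",
            len(table.otu_ids),
            len(table.sample_ids),
            simcfg.seed,
        )
        return table, records, tax, truth, dataclasses.asdict(simcfg)
    if "inputs" not in cfg:
        raise PipelineError("config", "config needs a 'simulate' or 'inputs' block")
    inputs = cfg["inputs"]
    for key in ("counts", "metadata"):
        if key not in inputs:
            raise PipelineError("config", f"inputs block is missing {key!r}")
    table = io.read_count_table(inputs["counts"])
    records = io.read_metadata(inputs["metadata"])
    tax = io.read_taxonomy(inputs["taxonomy"]) if "taxonomy" in inputs else None
    return table, records, tax, None, {"inputs": dict(inputs)}


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> dict:
    """Execute the full workflow; returns the run summary dict.

    Stage order follows the decontamination procedure: spurious-OTU removal
    on the full dataset, then the biomass gate, then contaminant
    identification and subtraction on the gated specimens.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    thresholds = {**DEFAULT_THRESHOLDS, **(cfg.get("thresholds") or {})}
    methods = list(cfg.get("decontam_methods") or ["ntconly", "combined"])
    seed = int(cfg.get("seed", cfg.get("simulate", {}).get("seed", 0) or 0))
    summary: dict[str, Any] = {"parameters": {"thresholds": thresholds, "seed": seed}}

    table, records, tax, truth, input_desc = _acquire_inputs(cfg, out_dir)
    summary["parameters"]["input"] = input_desc

    # --- QC ----------------------------------------------------------------
    qc_records = qcmod.compute_qc(table, records, thresholds["min_total_reads"])
    corr = qcmod.qc_correlations(qc_records)
    props_all = io.to_proportions(table)
    repro = qcmod.group_reproducibility(props_all, records)
    _write_qc(qc_records, repro, out_dir)
    summary["qc"] = {
        "n_samples": len(qc_records),
        "correlations": corr,
        "n_reproducibility_pairs": len(repro),
    }
    logger.info("qc: %d samples, %d repeat pairs", len(qc_records), len(repro))

    # --- denoise + gate (order fixed) --------------------------------------
    try:
        gated, manifest = dn.denoise_and_gate(
            table,
            records,
            thresholds["min_total_reads"],
            thresholds["biomass_cutoff"],
        )
    except ValueError as e:
        raise PipelineError("denoise", str(e)) from None
    summary["denoise"] = {
        k: v for k, v in manifest.items() if not isinstance(v, list)
    }
    io.write_count_table(gated, out_dir / "counts_denoised_gated.tsv")
    with (out_dir / "removal_manifest.tsv").open("w") as fh:
        fh.write("kind\tid\n")
        for o in manifest["removed_otus"]:
            fh.write(f"spurious_otu\t{o}\n")
        for s in manifest["excluded_samples"]:
            fh.write(f"low_biomass_sample\t{s}\n")
    logger.info(
        "denoise: removed %d OTUs, excluded %d samples",
        manifest["n_removed_otus"],
        manifest["n_excluded_samples"],
    )
    by_id = io.records_by_id(records)
    remaining_specimens = [
        s
        for s in gated.sample_ids
        if by_id[s].role == io.Role.SPECIMEN
    ]
    if not remaining_specimens:
        io.write_run_summary(summary, out_dir / "summary.json")
        raise PipelineError(
            "gate", "no specimens remain after denoising and gating"
        )

    # --- decontamination ----------------------------------------------------
    props = io.to_proportions(gated)
    reports: dict[str, io.ContaminantReport] = {}
    after: dict[str, io.ProportionTable] = {}
    summary["decontam"] = {}
    for method in methods:
        try:
            rep = dc.classify_contaminants(
                gated, props, records, method, thresholds["classifier_threshold"]
            )
        except ValueError as e:
            raise PipelineError("decontam", f"{method}: {e}") from None
        reports[method] = rep
        after[method] = dc.subtract_contaminants(props, rep, records)
        io.write_contaminant_report(rep, out_dir / f"contaminants_{method}.tsv")
        io.write_proportion_table(
            after[method], out_dir / f"proportions_after_{method}.tsv"
        )
        summary["decontam"][method] = {"n_contaminants": len(rep.contaminants)}
        logger.info("decontam[%s]: %d contaminants", method, len(rep.contaminants))
    if "ntconly" in reports and "combined" in reports:
        nt = set(reports["ntconly"].contaminants)
        cb = set(reports["combined"].contaminants)
        overlap = len(cb & nt) / len(cb) if cb else float("nan")
        # recorded, not asserted: frequency evidence needs no NTC presence,
        # so combined ⊆ ntconly is an empirical observation, not a law
        summary["decontam"]["combined_within_ntconly_fraction"] = overlap
    if tax is not None and len(after) > 0:
        shifts = dc.shift_report(props, after, tax)
        _write_shifts(shifts, out_dir)
        summary["decontam"]["n_shift_records"] = len(shifts)

    # --- diversity -----------------------------------------------------------
    try:
        dmat = dv.distance_matrix(props)
        dend = dv.complete_linkage(dmat)
        primary = dv.cut(dend, thresholds["cut_primary"])
        secondary = dv.cut(dend, thresholds["cut_secondary"])
        roles = {s: by_id[s].role.value for s in props.sample_ids}
        if len(set(roles.values())) >= 2:
            f_stat, p_val = dv.permanova(
                dmat, roles, thresholds["n_permutations"], seed
            )
        else:
            f_stat, p_val = float("nan"), float("nan")
    except ValueError as e:
        raise PipelineError("diversity", str(e)) from None
    with (out_dir / "clusters.tsv").open("w") as fh:
        fh.write("sample_id\tcluster_primary\tcluster_secondary\n")
        for s in props.sample_ids:
            fh.write(f"{s}\t{primary[s]}\t{secondary[s]}\n")
    summary["diversity"] = {
        "n_clusters_primary": len(set(primary.values())),
        "n_clusters_secondary": len(set(secondary.values())),
        "permanova_f_by_role": f_stat,
        "permanova_p_by_role": p_val,
    }

    # --- mock evaluation -----------------------------------------------------
    mock_ids = [s for s in table.sample_ids if by_id[s].role == io.Role.MOCK]
    if mock_ids and tax is not None:
        ref_name = cfg.get("mock_reference", "zymobiomics")
        ref = (
            sim.builtin_mock(ref_name)
            if ref_name in ("zymobiomics", "bei")
            else io.read_mock_reference(ref_name)
        )
        backgrounds = {
            s: me.background_proportion(props_all, s, ref, tax) for s in mock_ids
        }
        summary["mock_eval"] = {
            "reference": ref.name,
            "background_proportion": backgrounds,
        }

    io.write_run_summary(summary, out_dir / "summary.json")
    logger.info("pipeline complete: %s", out_dir / "summary.json")
    return summary


def _write_qc(qc_records, repro, out_dir: Path) -> None:
    with (out_dir / "qc.tsv").open("w") as fh:
        fh.write(
            "sample_id\tread_count\tshannon\totu_count\tspurious_count\t"
            "copies_per_ul\tage_days\n"
        )
        for r in qc_records:
            fh.write(
                f"{r.sample_id}\t{r.read_count}\t{r.shannon:.6f}\t{r.otu_count}\t"
                f"{r.spurious_count}\t{r.copies_per_ul:.6g}\t{r.age_days:.6g}\n"
            )
    with (out_dir / "reproducibility.tsv").open("w") as fh:
        fh.write("repeat_group\tsample_a\tsample_b\tr_squared\tsame_run\tundefined\n")
        for r in repro:
            fh.write(
                f"{r.repeat_group}\t{r.pair[0]}\t{r.pair[1]}\t{r.r_squared:.6f}\t"
                f"{int(r.same_run)}\t{int(r.undefined)}\n"
            )


def _write_shifts(shifts, out_dir: Path) -> None:
    methods = sorted(shifts[0].mean_after) if shifts else []
    with (out_dir / "shifts.tsv").open("w") as fh:
        cols = ["level", "taxon", "n_positive", "mean_before"]
        for m in methods:
            cols += [f"mean_after_{m}", f"fraction_removed_{m}"]
        fh.write("\t".join(cols) + "\n")
        for s in shifts:
            row = [s.level, s.taxon, str(s.n_positive), f"{s.mean_before:.6g}"]
            for m in methods:
                row += [
                    f"{s.mean_after[m]:.6g}",
                    f"{s.fraction_completely_removed[m]:.6g}",
                ]
            fh.write("\t".join(row) + "\n")
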