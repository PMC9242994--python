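"""Config-driven orchestration of the synthetic + analysis stages.

A pipeline config is a plain mapping (usually loaded from YAML) with a
master ``seed``, a ``stages`` list, and one optional parameter block per
stage.  Stage seeds are derived deterministically from the master seed
and the stage name, so a fixed config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import circorf, junction, screen, simulate

log = logging.getLogger(__name__)

STAGES = (
    "simulate_screen",
    "screen_score",
    "simulate_circrnas",
    "orf_call",
    "pepdb_build",
    "simulate_psms",
    "psm_filter",
)

_STAGE_KEYS: dict[str, set[str]] = {
    "simulate_screen": {
        "n_inserts",
        "planted_hexamers",
        "p_active",
        "p_background",
        "reads_per_fraction",
        "error_rate",
    },
    "screen_score": {"z_hi", "z_lo", "green", "dark"},
    "simulate_circrnas": {"n_corf", "n_rcorf", "n_noorf", "corf_aa", "circle_codons"},
    "orf_call": {"min_aa", "fasta"},
    "pepdb_build": {"min_len", "max_missed", "min_flank", "circs"},
    "simulate_psms": {"n_true", "violators", "reference_size"},
    "psm_filter": {"q_max", "min_len", "min_flank", "max_missed", "psms", "reference"},
}

_TOP_KEYS = {"seed", "stages"} | set(STAGES)


class PipelineConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping[str, Any]) -> None:
    if not isinstance(cfg, Mapping):
        raise PipelineConfigError("config must be a mapping")
    for key in cfg:
        if key not in _TOP_KEYS:
            raise PipelineConfigError(f"unknown config key: {key!r}")
    stages = cfg.get("stages", [])
    for stage in stages:
        if stage not in STAGES:
            raise PipelineConfigError(f"unknown stage: {stage!r}")
    for stage, block in cfg.items():
        if stage in STAGES:
            if not isinstance(block, Mapping):
                raise PipelineConfigError(f"stage block {stage!r} must be a mapping")
            for key in block:
                if key not in _STAGE_KEYS[stage]:
                    raise PipelineConfigError(
                        f"unknown key {key!r} in stage {stage!r}"
                    )


def stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def run_pipeline(cfg: Mapping[str, Any], out_dir) -> dict:
    """Execute the selected stages in dependency order; returns the run report."""
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    requested = list(cfg.get("stages", []))
    ordered = [s for s in STAGES if s in requested]
    ctx: dict[str, Any] = {}
    report: dict[str, Any] = {"seed": seed, "stages": {}}
    for stage in ordered:
        params = dict(cfg.get(stage, {}))
        log.info("pipeline: running stage %s", stage)
        counts = _RUNNERS[stage](params, stage_seed(seed, stage), ctx, out)
        report["stages"][stage] = {"params": params, "counts": counts}
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# stage runners: (params, seed, ctx, out_dir) -> counts dict


def _run_simulate_screen(params, seed, ctx, out: Path):
    cfg = simulate.ScreenSimConfig(seed=seed, **{
        k: tuple(v) if k == "planted_hexamers" else v for k, v in params.items()
    })
    sim = simulate.simulate_screen(cfg)
    simulate.write_screen_sim(sim, out / "screen")
    ctx["screen_sim"] = sim
    return {f"reads_{frac}": len(reads) for frac, reads in sim.reads.items()}


def _run_screen_score(params, seed, ctx, out: Path):
    z_hi = float(params.get("z_hi", screen.DEFAULT_Z_HI))
    z_lo = float(params.get("z_lo", screen.DEFAULT_Z_LO))
    if "screen_sim" in ctx:
        sim = ctx["screen_sim"]
        green_reads, dark_reads = sim.green_reads(), sim.dark_reads()
    else:
        green_reads = [r for p in params["green"] for r in simulate.read_fastq(p)]
        dark_reads = [r for p in params["dark"] for r in simulate.read_fastq(p)]
    green = screen.count_hexamers(screen.extract_inserts(green_reads, fraction_label="green"))
    dark = screen.count_hexamers(screen.extract_inserts(dark_reads, fraction_label="dark"))
    table = screen.score_table(green, dark, z_hi=z_hi, z_lo=z_lo)
    table.to_csv(out / "hexamer_scores.tsv", sep="\t", index=False)
    ctx["score_table"] = table
    return {
        "hexamers": len(table),
        "enriched": int((table["class"] == "enriched").sum()),
        "depleted": int((table["class"] == "depleted").sum()),
    }


def _run_simulate_circrnas(params, seed, ctx, out: Path):
    plan = simulate.CircSimPlan(seed=seed, **params)
    sim = simulate.simulate_circrnas(plan)
    simulate.write_circ_sim(sim, out / "circs")
    ctx["circ_sim"] = sim
    return {"circles": len(sim.circs)}


def _circles(params, ctx):
    if "circ_sim" in ctx:
        return ctx["circ_sim"].circs
    from .io import read_fasta

    return [circorf.CircRNA(id=k, seq=v) for k, v in read_fasta(params["fasta"]).items()]


def _run_orf_call(params, seed, ctx, out: Path):
    circs = _circles(params, ctx)
    min_aa = int(params.get("min_aa", circorf.DEFAULT_MIN_AA))
    rows = []
    for c in circs:
        for orf in circorf.find_circorfs(c, min_aa=min_aa):
            rows.append(
                {
                    "circ_id": c.id,
                    "start_offset": orf.start_offset,
                    "start_codon": orf.start_codon,
                    "type": orf.type,
                    "length_aa": orf.length_aa,
                    "crosses_junction": orf.crosses_junction,
                }
            )
    import pandas as pd

    pd.DataFrame(
        rows,
        columns=["circ_id", "start_offset", "start_codon", "type", "length_aa", "crosses_junction"],
    ).to_csv(out / "orfs.tsv", sep="\t", index=False)
    return {"circles": len(circs), "orfs": len(rows)}


def _run_pepdb_build(params, seed, ctx, out: Path):
    circs = _circles({"fasta": params.get("circs")}, ctx)
    db = junction.build_junction_db(
        circs,
        min_len=int(params.get("min_len", junction.DEFAULT_MIN_PEPTIDE_LEN)),
        max_missed=int(params.get("max_missed", junction.DEFAULT_MAX_MISSED)),
        min_flank=int(params.get("min_flank", junction.DEFAULT_MIN_FLANK)),
    )
    junction.write_junction_fasta(db, out / "junction_db.fa")
    ctx["junction_db"] = db
    return {"peptides": len(db)}


def _run_simulate_psms(params, seed, ctx, out: Path):
    db = ctx.get("junction_db")
    if db is None:
        raise PipelineConfigError("simulate_psms requires the pepdb_build stage")
    reference = simulate.simulate_reference_proteome(
        n_proteins=int(params.get("reference_size", 20)), seed=stage_seed(seed, "ref")
    )
    plan = simulate.PsmSimPlan(
        n_true=int(params.get("n_true", 10)),
        violators=tuple(params.get("violators", simulate.VIOLATOR_KINDS)),
        seed=seed,
    )
    sim = simulate.simulate_psms(db, reference, plan)
    simulate.write_psm_sim(sim, out / "psms")
    from .io import write_fasta

    write_fasta(reference, out / "psms" / "reference.fa")
    ctx["psm_sim"] = sim
    ctx["reference"] = reference
    return {"psms": len(sim.psms)}


def _run_psm_filter(params, seed, ctx, out: Path):
    if "psm_sim" in ctx:
        sim = ctx["psm_sim"]
        psms, index, reference = sim.psms, sim.junction_index, ctx["reference"]
    else:
        from .io import read_fasta

        psms = junction.read_psm_tsv(params["psms"])
        reference = read_fasta(params["reference"])
        db = ctx.get("junction_db")
        if db is None:
            raise PipelineConfigError("psm_filter needs a junction database in context")
        index = db.junction_index()
    surviving, rep = junction.filter_psms(
        psms,
        reference,
        index,
        q_max=float(params.get("q_max", junction.DEFAULT_Q_MAX)),
        min_len=int(params.get("min_len", junction.DEFAULT_MIN_PEPTIDE_LEN)),
        min_flank=int(params.get("min_flank", junction.DEFAULT_MIN_FLANK)),
        max_missed=int(params.get("max_missed", junction.DEFAULT_MAX_MISSED)),
    )
    junction.write_psm_tsv(surviving, out / "psms_filtered.tsv")
    rep.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    return {"surviving": len(surviving)}


_RUNNERS = {
    "simulate_screen": _run_simulate_screen,
    "screen_score": _run_screen_score,
    "simulate_circrnas": _run_simulate_circrnas,
    "orf_call": _run_orf_call,
    "pepdb_build": _run_pepdb_build,
    "simulate_psms": _run_simulate_psms,
    "psm_filter": _run_psm_filter,
}
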