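"""End-to-end orchestration: simulate -> dosage -> gates -> motif -> metagene.

Stages communicate through on-disk artifacts in plain-text formats so
each stage can be rerun or replaced independently. A run is fully
determined by its YAML config (including the seed): rerunning the same
config reproduces report.json byte for byte. Wall-clock timings and
file hashes go to run.log only, never into the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import SyntheticConfig
from .dosage import call_deregulated, moderated_t
from .gates import classify_maturation, gate_crosstab
from .io import read_fixture, write_fixture
from .metagene import condense_samples, group_profiles, metagene_matrix, stop_region_ttest
from .motif import build_occurrence_matrix, dedupe_and_rank, enrichment_test, positional_profile, select_sets
from .simulate import simulate_cohort

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "simulate": {"n_genes": 6000},
    "dosage": {"fc_min": 2.0, "p_max": 0.05, "p_comparison": "strict",
               "use_adjusted": False},
    "maturation": {"fc_min": 2.0, "p_max": 0.05, "p_comparison": "inclusive",
                   "use_adjusted": False},
    "motif": {"set_size": 1000, "flank_len": 400, "pattern": "GAC[UA]",
              "smoother": "spline", "region_half_width": 50},
    "metagene": {"body_bins": 100, "flank_nt": 400, "flank_bin_nt": 10,
                 "mode": "binary", "min_score": None},
}

_KNOWN_BLOCKS = {"seed", "out_dir", "simulate", "paths", "dosage", "maturation",
                 "motif", "metagene"}


def load_config(source) -> dict:
    """Load a config from a YAML path / mapping, filling in defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if "paths" in raw and "simulate" not in raw:
        cfg.pop("simulate")
    for key, value in raw.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def validate_config(config) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    try:
        cfg = load_config(config)
    except Exception as exc:  # unparseable file is a single fatal problem
        return [f"config unreadable: {exc}"]
    for key in cfg:
        if key not in _KNOWN_BLOCKS:
            problems.append(f"unknown config block {key!r}")
    has_sim = "simulate" in cfg
    has_paths = "paths" in cfg
    if not has_sim and not has_paths:
        problems.append("config needs either a 'simulate' or a 'paths' block")
    if has_sim:
        if "seed" not in cfg:
            problems.append("seed: required whenever a simulate block is present")
        try:
            SyntheticConfig.from_dict(
                {**cfg["simulate"], "seed": cfg.get("seed", 0)}
            )
        except (TypeError, ValueError) as exc:
            problems.append(f"simulate: {exc}")
    if has_paths:
        for field in ("fasta", "annotation", "expression", "peaks"):
            p = cfg["paths"].get(field)
            if p is None:
                problems.append(f"paths.{field}: missing")
            elif not Path(p).exists():
                problems.append(f"paths.{field}: file not found: {p}")
    for block in ("dosage", "maturation"):
        b = cfg.get(block, {})
        if b.get("fc_min", 2.0) < 1:
            problems.append(f"{block}.fc_min: must be >= 1")
        if not 0 < b.get("p_max", 0.05) <= 1:
            problems.append(f"{block}.p_max: must be in (0, 1]")
        if b.get("p_comparison", "strict") not in ("strict", "inclusive"):
            problems.append(f"{block}.p_comparison: must be strict or inclusive")
    motif = cfg.get("motif", {})
    if motif.get("set_size", 1000) < 1:
        problems.append("motif.set_size: must be >= 1")
    if has_sim:
        n = cfg["simulate"].get("n_genes", DEFAULT_CONFIG["simulate"]["n_genes"])
        if n < 3 * motif.get("set_size", 1000):
            problems.append(
                "simulate.n_genes: must be >= 3 * motif.set_size for "
                "disjoint up/down/center sets"
            )
    mg = cfg.get("metagene", {})
    if mg.get("flank_nt", 400) % mg.get("flank_bin_nt", 10):
        problems.append("metagene.flank_nt: must be a multiple of flank_bin_nt")
    if mg.get("mode", "binary") not in ("binary", "score"):
        problems.append("metagene.mode: must be binary or score")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _round(x: float, digits: int = 12) -> float:
    return float(round(float(x), digits))


class StageFailure(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config, out_dir=None) -> dict:
    """Run all stages, writing artifacts under ``out_dir``; returns the report."""
    cfg = load_config(config)
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(out_dir or cfg.get("out_dir", "results/run"))
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("matdosage")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    report: dict = {"version": __version__, "config": cfg, "stages": {}}
    timer: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                root.removeHandler(handler)
                raise StageFailure(name, exc) from exc
            timer[name] = time.perf_counter() - t0
            logger.info("stage %s finished in %.2f s", name, timer[name])
        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        if "simulate" in cfg:
            syn = SyntheticConfig.from_dict({**cfg["simulate"], "seed": cfg["seed"]})
            cohort = simulate_cohort(syn)
            manifest = write_fixture(
                cohort.study, cohort.transcripts, cohort.models, cohort.peaks,
                out / "fixture", force=True,
            )
            for name, path in manifest.items():
                logger.info("fixture %s: %s sha256=%s", name, path, _sha256(path))
        else:
            from .io import read_annotation, read_expression, read_fasta
            from .metagene import read_peaks_bed
            from .records import SimulatedCohort

            paths = cfg["paths"]
            sequences = read_fasta(paths["fasta"])
            records, models = read_annotation(paths["annotation"], sequences)
            cohort = SimulatedCohort(
                transcripts=records,
                models=models,
                study=read_expression(paths["expression"]),
                peaks=read_peaks_bed(paths["peaks"]),
            )
        state["cohort"] = cohort
        report["stages"]["simulate"] = {
            "n_genes": len(cohort.study.matrix),
            "n_transcripts": len(cohort.transcripts),
            "n_peaks": len(cohort.peaks),
        }

    @stage("dosage")
    def _dosage():
        study = state["cohort"].study
        ko = moderated_t(
            study.submatrix("MII", "CTL"), study.submatrix("MII", "mCKO")
        )
        table, counts = call_deregulated(ko, **cfg["dosage"])
        table.to_csv(out / "dosage_ko.tsv", sep="\t")
        mat = moderated_t(
            study.submatrix("GV", "CTL"), study.submatrix("MII", "CTL")
        )
        classes = classify_maturation(mat, **cfg["maturation"])
        mat_out = mat.copy()
        mat_out["maturation_class"] = classes
        mat_out.to_csv(out / "dosage_maturation.tsv", sep="\t")
        state["ko"], state["classes"] = table, classes
        report["stages"]["dosage"] = {
            **counts,
            "ko_prior_d0": _round(ko.attrs["prior_d0"])
            if ko.attrs["prior_d0"] != float("inf") else "inf",
            "ko_prior_s0_sq": _round(ko.attrs["prior_s0_sq"]),
        }

    @stage("gates")
    def _gates():
        gt = gate_crosstab(state["ko"]["call"], state["classes"])
        gt.table.to_csv(out / "gates.tsv", sep="\t")
        report["stages"]["gates"] = {
            "table": {r: {c: int(gt.table.loc[r, c]) for c in gt.table.columns}
                      for r in gt.table.index},
            "up_row_fractions": {
                c: _round(v) for c, v in gt.up_row_fractions.items()
            },
        }

    @stage("motif")
    def _motif():
        mcfg = cfg["motif"]
        cohort = state["cohort"]
        transcripts = {t.transcript_id: t for t in cohort.transcripts}
        results = pd.DataFrame(
            {
                "transcript_id": [t.transcript_id for t in cohort.transcripts],
                "gene_id": [t.gene_id for t in cohort.transcripts],
                "log2FC": state["ko"]["log2FC"]
                .reindex([t.gene_id for t in cohort.transcripts])
                .to_numpy(),
            }
        )
        ranked = dedupe_and_rank(
            results, {t.transcript_id: t.sequence for t in cohort.transcripts}
        )
        sets = select_sets(ranked, set_size=mcfg["set_size"])
        state["sets"] = sets
        flank = mcfg["flank_len"]
        half = mcfg["region_half_width"]
        region = (flank - half, flank + half)
        enrich: dict = {}
        occ_by_anchor: dict = {}
        for anchor in ("stop_codon", "start_codon"):
            occ = {
                label: build_occurrence_matrix(
                    members, transcripts, anchor=anchor, flank_len=flank,
                    pattern=mcfg["pattern"], set_label=label,
                )
                for label, members in sets.items()
            }
            occ_by_anchor[anchor] = occ
            prof_rows = {}
            for label, om in occ.items():
                prof = positional_profile(om, smoother=mcfg["smoother"])
                prof_rows[f"raw_{label}"] = prof.raw
                prof_rows[f"smoothed_{label}"] = prof.smoothed
            pd.DataFrame(prof_rows, index=pd.Index(
                prof.offsets, name="offset")).to_csv(
                out / f"motif_profile_{anchor}.tsv", sep="\t"
            )
            for label in ("up", "down"):
                res = enrichment_test(occ[label], occ["center"], region=region)
                enrich[f"{label}_vs_center_{anchor}"] = {
                    "p_value": _round(res.p_value),
                    "k": res.k, "K": res.K, "n": res.n, "N": res.N,
                    "region": list(res.region),
                }
        state["occ"] = occ_by_anchor
        with open(out / "motif_enrichment.json", "w") as fh:
            json.dump(enrich, fh, indent=2, sort_keys=True)
        report["stages"]["motif"] = {
            "matrix_shape": list(occ_by_anchor["stop_codon"]["up"].shape),
            "enrichment": enrich,
        }

    @stage("metagene")
    def _metagene():
        mg = cfg["metagene"]
        cohort = state["cohort"]
        track = condense_samples(cohort.peaks, min_score=mg["min_score"])
        gene_sets = {
            label: list(members["gene_id"]) for label, members in state["sets"].items()
        }
        in_sets = set().union(*gene_sets.values())
        models = [m for m in cohort.models if m.gene_id in in_sets]
        mm = metagene_matrix(
            models, track, body_bins=mg["body_bins"], flank_nt=mg["flank_nt"],
            flank_bin_nt=mg["flank_bin_nt"], mode=mg["mode"],
        )
        mm.values.to_csv(out / "metagene_matrix.tsv", sep="\t")
        profs = group_profiles(mm, gene_sets)
        wide = pd.concat(
            {name: df for name, df in profs.items()}, axis=1
        )
        wide.columns = ["_".join(c) for c in wide.columns]
        wide.to_csv(out / "metagene_profiles.tsv", sep="\t")
        tests = {}
        for label in ("up", "down"):
            res = stop_region_ttest(mm, gene_sets[label], gene_sets["center"])
            tests[f"{label}_vs_center_stop_flank"] = {
                "t": _round(res.t), "df": _round(res.df),
                "p_value": _round(res.p_value),
                "n_A": res.n_A, "n_B": res.n_B,
            }
        with open(out / "metagene_tests.json", "w") as fh:
            json.dump(tests, fh, indent=2, sort_keys=True)
        report["stages"]["metagene"] = {
            "n_profiled_genes": int(mm.values.shape[0]),
            "n_condensed_intervals": track.n_intervals(),
            "tests": tests,
        }

    report_json = out / "report.json"
    with open(report_json, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "report.md").write_text(render_report_md(report))
    logger.info("report sha256=%s", _sha256(report_json))
    for name, dt in timer.items():
        logger.info("timing %s: %.2f s", name, dt)
    root.removeHandler(handler)
    handler.close()
    return report


def render_report_md(report: dict) -> str:
    """Human-readable rendering of the run report (same numbers as the JSON)."""
    lines = [
        "# matdosage run report",
        "",
        f"* version: {report['version']}",
        f"* seed: {report['config'].get('seed')}",
        "",
    ]
    for stage, payload in report["stages"].items():
        lines.append(f"## {stage}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(payload, indent=2, sort_keys=True))
        lines.append("```")
        lines.append("")
    return "\n".join(lines)
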