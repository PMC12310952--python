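"""Stage orchestration: run pipeline stages in dependency order over an
output directory of on-disk intermediates, with a reproducibility manifest.

Stages: ``simulate`` (or ``extract`` from FASTQ) -> ``filter`` -> ``clones``
-> ``coupling`` / ``composition``; ``stability`` and ``score`` consume the
expression matrix.  Re-running a stage with unchanged inputs and seed is
byte-identical; every stochastic stage records its seed in the manifest.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .barcode_io import build_matrix, extract_barcodes, filter_triples, read_triples
from .clones import (
    attach_annotations,
    call_clones_per_dataset,
    clone_size_stats,
    dendrogram_newick,
)
from .composition import (
    classify_clone_fates,
    clone_category_fractions,
    fate_fractions,
    fate_table,
    upset_intersections,
)
from .coupling import LineageCoupling
from .expression import PCADistance, lognormalize, module_score, read_expression_mtx
from .simulate import (
    DEFAULT_FLANK3,
    DEFAULT_FLANK5,
    SimulationConfig,
    simulate_experiment,
    simulate_null,
    write_experiment,
    write_fastq,
)

log = logging.getLogger("clonetrace")

STAGES = ("simulate", "extract", "filter", "clones", "coupling", "composition",
          "stability", "score")
#: stages run by the ``all`` subcommand (expression stages need extra inputs)
DEFAULT_STAGES = ("simulate", "filter", "clones", "coupling", "composition")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"null": False, "fastq": None},
    "extract": {
        "fastq": None,
        "flank5": DEFAULT_FLANK5,
        "flank3": DEFAULT_FLANK3,
        # inserts shorter than 37 bp are excluded
        "min_len": 37,
        "flank_mismatch_tol": 0,
    },
    "filter": {
        # triples need >= 10 supporting reads; pairs >= 6 distinct UMIs
        "min_reads": 10,
        "min_umis": 6,
    },
    "clones": {
        # dendrogram cut on Jaccard distance; the principal sensitivity knob
        "cut_height": 0.5,
        "cross_dataset": False,
        "newick": False,
    },
    "coupling": {
        "state_col": "cell_type",
        # a clone is "shared" with >= 2 cells of each state
        "min_cells": 2,
        # 10,000 permutations define the null
        "n_permutations": 10_000,
        "stratify_col": None,
        "heatmap": False,
    },
    "composition": {
        "presence_min": 1,
        "groups": {
            "Astrocyte": ["Olig2_astro", "S100a11_astro"],
            "Exc_neuron": ["Ex_neuron"],
        },
        "precedence": [
            ["olig2_lineage", ["Olig2_astro"]],
            ["s100a11_lineage", ["S100a11_astro"]],
            ["neuron_linked", ["Ex_neuron"]],
        ],
        "fallback": "self_renewing",
        "eligible_states": None,
        "eligible_min": 1,
    },
    "stability": {
        "ref_time": None,
        "times": None,
        "subtypes": None,
        # the first 30 principal components are used
        "n_components": 30,
        "n_scrambles": 20,
        "mode": "pairwise",
    },
    "score": {"gene_sets": None, "n_bins": 24, "n_ctrl": 100},
}


class ConfigError(ValueError):
    """Config schema violation; the message carries the path into the config."""


def merge_config(user: Optional[dict]) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (user or {}).items():
        if key == "seed":
            cfg["seed"] = val
            continue
        if key not in cfg:
            raise ConfigError(f"config.{key}: unknown section (known: {sorted(cfg)})")
        if key == "simulate":
            cfg[key].update(val or {})
            continue
        for k2, v2 in (val or {}).items():
            if k2 not in cfg[key]:
                raise ConfigError(
                    f"config.{key}.{k2}: unknown option (known: {sorted(cfg[key])})"
                )
            cfg[key][k2] = v2
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    if not isinstance(cfg["seed"], int) or cfg["seed"] < 0:
        raise ConfigError("config.seed: must be a non-negative integer")
    f = cfg["filter"]
    if f["min_reads"] < 1:
        raise ConfigError(
            "config.filter.min_reads: must be >= 1 — triples are kept only with "
            "a minimum read support (default 10 reads)"
        )
    if f["min_umis"] < 1:
        raise ConfigError(
            "config.filter.min_umis: must be >= 1 — pairs are kept only with a "
            "minimum of distinct UMIs (default 6)"
        )
    if not 0 < cfg["clones"]["cut_height"] <= 1:
        raise ConfigError("config.clones.cut_height: must be in (0, 1]")
    if cfg["coupling"]["n_permutations"] < 2:
        raise ConfigError("config.coupling.n_permutations: must be >= 2 (default 10000)")
    if cfg["coupling"]["min_cells"] < 1:
        raise ConfigError("config.coupling.min_cells: must be >= 1 (default 2)")
    if cfg["extract"]["min_len"] < 1:
        raise ConfigError("config.extract.min_len: must be >= 1 (default 37 bp)")
    if cfg["stability"]["n_components"] < 1:
        raise ConfigError("config.stability.n_components: must be >= 1 (default 30)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing intermediate {path.name}: run the '{producer}' stage first"
        )
    return path


# ---------------------------------------------------------------------------
# stages — each returns {output name: path}


def stage_simulate(cfg: dict, outdir: Path) -> dict:
    sim_kwargs = {k: v for k, v in cfg["simulate"].items() if k not in ("null", "fastq")}
    sim_kwargs.setdefault("seed", cfg["seed"])
    config = SimulationConfig.from_dict(sim_kwargs)
    sim = (simulate_null if cfg["simulate"].get("null") else simulate_experiment)(config)
    paths = write_experiment(sim, outdir)
    if cfg["simulate"].get("fastq"):
        fq = outdir / "reads.fastq.gz"
        n = write_fastq(sim, fq, cfg["extract"]["flank5"], cfg["extract"]["flank3"])
        log.info("simulate: wrote %d FASTQ reads", n)
        paths["fastq"] = str(fq)
    log.info(
        "simulate: %d cells, %d clones, %d triples",
        len(sim.annotations), len(sim.truth.clones), len(sim.triples),
    )
    return paths


def stage_extract(cfg: dict, outdir: Path) -> dict:
    e = cfg["extract"]
    fastq = e.get("fastq") or str(outdir / "reads.fastq.gz")
    _require(Path(fastq), "simulate (with fastq: true) or provide extract.fastq")
    ann = pd.read_csv(_require(outdir / "annotations.csv", "simulate"))
    triples, report = extract_barcodes(
        fastq,
        flank5=e["flank5"],
        flank3=e["flank3"],
        min_len=e["min_len"],
        whitelist=set(ann["cell_id"]),
        flank_mismatch_tol=e["flank_mismatch_tol"],
    )
    log.info(
        "extract: %d reads in, %d kept (%d missing flank, %d short, %d off-whitelist)",
        report.n_reads, report.n_kept, report.n_missing_flank,
        report.n_short_insert, report.n_not_whitelisted,
    )
    triples.to_csv(outdir / "triples.tsv", sep="\t", index=False)
    (outdir / "extract_report.json").write_text(
        json.dumps(report.__dict__, indent=2) + "\n"
    )
    return {"triples": str(outdir / "triples.tsv"),
            "extract_report": str(outdir / "extract_report.json")}


def stage_filter(cfg: dict, outdir: Path) -> dict:
    triples = read_triples(_require(outdir / "triples.tsv", "simulate or extract"))
    pairs, report = filter_triples(
        triples, min_reads=cfg["filter"]["min_reads"], min_umis=cfg["filter"]["min_umis"]
    )
    log.info(
        "filter: %d triples -> %d pass reads>=%d; %d pairs -> %d pass umis>=%d",
        report.n_triples_in, report.n_triples_read_pass, report.min_reads,
        report.n_pairs_in, report.n_pairs_umi_pass, report.min_umis,
    )
    ann_path = outdir / "annotations.csv"
    whitelist = pd.read_csv(ann_path)["cell_id"] if ann_path.exists() else None
    matrix = build_matrix(pairs, whitelist=whitelist)
    log.info("filter: matrix %dx%d, %d whitelisted cells without barcodes dropped",
             *matrix.shape, matrix.n_dropped_cells)
    pairs.to_csv(outdir / "pairs.csv", index=False)
    matrix.to_long_csv(outdir / "matrix_long.csv")
    matrix.to_mtx(outdir / "matrix")
    rep = dict(report.__dict__, n_dropped_cells=matrix.n_dropped_cells)
    (outdir / "filter_report.json").write_text(json.dumps(rep, indent=2) + "\n")
    return {
        "pairs": str(outdir / "pairs.csv"),
        "matrix_long": str(outdir / "matrix_long.csv"),
        "matrix_mtx": str(outdir / "matrix.mtx"),
        "filter_report": str(outdir / "filter_report.json"),
    }


def stage_clones(cfg: dict, outdir: Path) -> dict:
    from .barcode_io import CellBarcodeMatrix

    matrix = CellBarcodeMatrix.from_mtx(_require(outdir / "matrix.mtx", "filter").with_suffix(""))
    ann = pd.read_csv(_require(outdir / "annotations.csv", "simulate"))
    clones = call_clones_per_dataset(
        matrix, ann,
        cut_height=cfg["clones"]["cut_height"],
        cross_dataset=cfg["clones"]["cross_dataset"],
    )
    clones = attach_annotations(clones, ann)
    stats = clone_size_stats(clones)
    log.info("clones: %d clones, mean size %.2f (cut_height=%.2f)",
             stats.n_clones, stats.mean_size, cfg["clones"]["cut_height"])
    clones.to_csv(outdir / "clones.csv", index=False)
    (outdir / "clone_stats.json").write_text(json.dumps({
        "n_clones": stats.n_clones,
        "mean_size": stats.mean_size,
        "cut_height": cfg["clones"]["cut_height"],
        "size_histogram": {int(k): int(v) for k, v in stats.size_histogram.items()},
    }, indent=2) + "\n")
    out = {"clones": str(outdir / "clones.csv"),
           "clone_stats": str(outdir / "clone_stats.json")}
    if cfg["clones"]["newick"]:
        (outdir / "dendrogram.nwk").write_text(dendrogram_newick(matrix) + "\n")
        out["dendrogram"] = str(outdir / "dendrogram.nwk")
    return out


def stage_coupling(cfg: dict, outdir: Path) -> dict:
    clones = pd.read_csv(_require(outdir / "clones.csv", "clones"))
    c = cfg["coupling"]
    model = LineageCoupling(
        clones, state_col=c["state_col"], min_cells=c["min_cells"],
        stratify_col=c["stratify_col"],
    )
    res = model.fit(n_permutations=c["n_permutations"], seed=cfg["seed"])
    paths = res.to_csv_dir(outdir)
    if c["heatmap"]:
        res.plot_heatmap("zscores", str(outdir / "coupling_zscores.png"))
        paths["heatmap"] = str(outdir / "coupling_zscores.png")
    log.info("coupling: %d states, %d permutations", len(res.states), res.n_permutations)
    return paths


def stage_composition(cfg: dict, outdir: Path) -> dict:
    clones = pd.read_csv(_require(outdir / "clones.csv", "clones"))
    c = cfg["composition"]
    state_col = cfg["coupling"]["state_col"]
    ft = fate_table(clones, state_col=state_col)
    ft.to_csv(outdir / "fate_table.csv")
    out = {"fate_table": str(outdir / "fate_table.csv")}
    if c["groups"]:
        frac = clone_category_fractions(
            clones, {k: list(v) for k, v in c["groups"].items()},
            presence_min=c["presence_min"], state_col=state_col,
        )
        frac.to_csv(outdir / "category_fractions.csv", index=False)
        out["category_fractions"] = str(outdir / "category_fractions.csv")
        states = [s for sts in c["groups"].values() for s in sts]
        ups = upset_intersections(
            clones, states, presence_min=c["presence_min"], state_col=state_col
        )
        ups.to_csv(outdir / "upset_intersections.csv", index=False)
        out["upset"] = str(outdir / "upset_intersections.csv")
    if c["precedence"]:
        cats = classify_clone_fates(
            clones, [(n, list(s)) for n, s in c["precedence"]],
            fallback=c["fallback"], eligible_states=c["eligible_states"],
            eligible_min=c["eligible_min"], presence_min=c["presence_min"],
            state_col=state_col,
        )
        cats.to_csv(outdir / "fate_categories.csv", index=False)
        fate_fractions(cats).rename("fraction").to_csv(outdir / "fate_fractions.csv")
        out["fate_categories"] = str(outdir / "fate_categories.csv")
        out["fate_fractions"] = str(outdir / "fate_fractions.csv")
    return out


def _load_expression(outdir: Path):
    ann = pd.read_csv(_require(outdir / "annotations.csv", "simulate"))
    return read_expression_mtx(
        _require(outdir / "expression.mtx", "simulate"),
        outdir / "expression.genes.txt",
        outdir / "expression.cells.txt",
        annotations=ann,
    )


def stage_stability(cfg: dict, outdir: Path) -> dict:
    s = cfg["stability"]
    if s["ref_time"] is None:
        raise ConfigError("config.stability.ref_time: required for the stability stage")
    adata = lognormalize(_load_expression(outdir))
    res = PCADistance(adata).fit(
        ref_time=s["ref_time"], times=s["times"], subtypes=s["subtypes"],
        n_components=s["n_components"], n_scrambles=s["n_scrambles"],
        seed=cfg["seed"], mode=s["mode"],
    )
    res.table.to_csv(outdir / "stability.csv", index=False)
    return {"stability": str(outdir / "stability.csv")}


def stage_score(cfg: dict, outdir: Path) -> dict:
    s = cfg["score"]
    if not s["gene_sets"]:
        raise ConfigError("config.score.gene_sets: required (mapping name -> gene list)")
    adata = lognormalize(_load_expression(outdir))
    scores = pd.DataFrame(index=adata.obs_names)
    for name, genes in s["gene_sets"].items():
        scores[name] = module_score(
            adata, list(genes), n_bins=s["n_bins"], n_ctrl=s["n_ctrl"], seed=cfg["seed"]
        )
    scores.index.name = "cell_id"
    scores.to_csv(outdir / "module_scores.csv")
    return {"module_scores": str(outdir / "module_scores.csv")}


_STAGE_FN = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "filter": stage_filter,
    "clones": stage_clones,
    "coupling": stage_coupling,
    "composition": stage_composition,
    "stability": stage_stability,
    "score": stage_score,
}


def run_pipeline(config: Optional[dict], outdir: str | Path, stages) -> dict:
    """Run ``stages`` in order over ``outdir``; returns the run manifest."""
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": "+".join(stages),
        "package_version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "stages": {},
    }
    for stage in stages:
        if stage not in _STAGE_FN:
            raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
        outputs = _STAGE_FN[stage](cfg, outdir)
        manifest["stages"][stage] = {
            name: {"path": p, "sha256": _sha256(Path(p))} for name, p in outputs.items()
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
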