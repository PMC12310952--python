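"""Synthetic dual-progenitor lineage-barcoding experiments.

This module generates TrackerSeq-style clonal data with known ground truth so
every downstream stage (barcode filtering, clone calling, coupling statistics,
composition summaries, expression scores) can be tested against the generative
parameters.

The default configuration emulates a dual radial-glia (RGC) experiment: two
progenitor subtypes found clones whose *fate category* is drawn from a
subtype-specific profile (RGC_1 ~90% neuron-linked with 5% in each astrocyte
lineage; RGC_2 ~50% Olig2-lineage, 34% self-renewing, 16% neuron-linked and
none in the S100a11 lineage), clones average ~4.5 cells, each founder carries
one or more integration barcodes drawn with replacement from a library of 1e5
variants, and barcodes are recovered in ~75% of cells.

Fate categories are assigned at the clone level and member cell types are then
sampled from a category-specific mixture.  A clone of size >= 2 in a
lineage-linked category always contains its residual progenitor and at least
one cell of the defining lineage type, so the clone-level category is
faithfully readable from member cell types (a size-1 clone consists of the
single defining cell, or of the progenitor for self-renewing clones).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .distributions import DistSpec

_BASES = np.array(list("ACGT"))

#: default mixture weight of the residual progenitor among non-guaranteed cells
DEFAULT_RESIDUAL_PROGENITOR_FRAC = 0.40

DEFAULT_FATE_PROFILE: Dict[str, Dict[str, float]] = {
    "RGC_1": {
        "neuron_linked": 0.90,
        "olig2_lineage": 0.05,
        "s100a11_lineage": 0.05,
        "self_renewing": 0.0,
    },
    "RGC_2": {
        "olig2_lineage": 0.50,
        "self_renewing": 0.34,
        "neuron_linked": 0.16,
        "s100a11_lineage": 0.0,
    },
}

#: fate category -> the cell type that defines it (None = progenitor-only clone)
DEFAULT_FATE_DEFINING_TYPE: Dict[str, Optional[str]] = {
    "neuron_linked": "Ex_neuron",
    "olig2_lineage": "Olig2_astro",
    "s100a11_lineage": "S100a11_astro",
    "self_renewing": None,
}


def _check_prob_vector(p: np.ndarray, what: str) -> None:
    if np.any(p < 0):
        raise ValueError(f"{what}: negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{what}: probabilities sum to {p.sum()}, not 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated lineage-tracing experiment.

    All stochastic behaviour is governed by ``seed``: a fixed seed reproduces
    every output table byte-for-byte.
    """

    n_progenitors_per_subtype: Dict[str, int] = field(
        default_factory=lambda: {"RGC_1": 250, "RGC_2": 250}
    )
    fate_profile: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FATE_PROFILE.items()}
    )
    fate_defining_type: Dict[str, Optional[str]] = field(
        default_factory=lambda: dict(DEFAULT_FATE_DEFINING_TYPE)
    )
    residual_progenitor_frac: float = DEFAULT_RESIDUAL_PROGENITOR_FRAC
    clone_size_dist: DistSpec = field(
        default_factory=lambda: DistSpec("ztpoisson", {"mean": 4.5})
    )
    barcode_library_size: int = 100_000
    barcode_length: int = 40
    integrations_per_cell_dist: DistSpec = field(
        default_factory=lambda: DistSpec("ztpoisson", {"mean": 2.0})
    )
    barcode_recovery_rate: float = 0.75
    umi_per_pair_dist: DistSpec = field(
        default_factory=lambda: DistSpec("ztnbinom", {"mean": 20.0, "size": 10.0})
    )
    reads_per_triple_dist: DistSpec = field(
        default_factory=lambda: DistSpec("ztnbinom", {"mean": 25.0, "size": 2.0})
    )
    n_genes: int = 500
    n_marker_genes_per_type: int = 20
    expression_effect_size: float = 1.0
    dispersion: float = 2.0
    timepoint: str = "E18.5"
    dataset: str = "sim0"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_progenitors_per_subtype:
            raise ValueError("need at least one progenitor subtype")
        for st, n in self.n_progenitors_per_subtype.items():
            if n <= 0:
                raise ValueError(f"n_progenitors_per_subtype[{st!r}] must be positive")
            if st not in self.fate_profile:
                raise ValueError(f"no fate profile for subtype {st!r}")
            probs = self.fate_profile[st]
            unknown = set(probs) - set(self.fate_defining_type)
            if unknown:
                raise ValueError(f"fate categories without defining type: {unknown}")
            _check_prob_vector(
                np.array(list(probs.values()), dtype=float), f"fate_profile[{st!r}]"
            )
        if not 0.0 < self.barcode_recovery_rate <= 1.0:
            raise ValueError("barcode_recovery_rate must be in (0, 1]")
        if not 0.0 <= self.residual_progenitor_frac < 1.0:
            raise ValueError("residual_progenitor_frac must be in [0, 1)")
        for name in ("barcode_library_size", "barcode_length", "n_genes", "n_marker_genes_per_type"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.barcode_length < 37:
            raise ValueError("barcode_length must be >= 37 (length-filterable)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def cell_types(self) -> list:
        """All cell-type labels the configuration can emit, sorted."""
        types = set(self.n_progenitors_per_subtype)
        types.update(t for t in self.fate_defining_type.values() if t is not None)
        return sorted(types)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("clone_size_dist", "integrations_per_cell_dist",
                  "umi_per_pair_dist", "reads_per_triple_dist"):
            d[k] = getattr(self, k).to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("clone_size_dist", "integrations_per_cell_dist",
                  "umi_per_pair_dist", "reads_per_triple_dist"):
            if k in d and isinstance(d[k], dict):
                d[k] = DistSpec.from_dict(d[k])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``cells``: one row per cell — cell_id, clone_id, founder_subtype,
    cell_type, timepoint, recovered (did the cell emit any triple).
    ``clones``: one row per clone — clone_id, founder_subtype, fate_category,
    size, barcodes (';'-joined integration barcode set).
    """

    cells: pd.DataFrame
    clones: pd.DataFrame


@dataclass
class SimulatedExperiment:
    """Bundle returned by :func:`simulate_experiment`."""

    triples: pd.DataFrame  # cell_bc, umi, lineage_bc, reads
    annotations: pd.DataFrame  # cell_id, cell_type, subtype, timepoint, dataset
    adata: ad.AnnData  # raw counts, cells x genes
    truth: SimTruth
    config: SimulationConfig


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    idx = rng.integers(0, 4, size=(n, length))
    return np.array(["".join(row) for row in _BASES[idx]])


def _barcode_sequence(library_entropy: int, index: int, length: int) -> str:
    """Deterministic sequence for library member ``index`` (stable across draws)."""
    r = np.random.default_rng(np.random.SeedSequence([library_entropy, int(index)]))
    return "".join(_BASES[r.integers(0, 4, size=length)])


def _sample_clone_types(
    rng: np.random.Generator,
    size: int,
    founder: str,
    category: str,
    config: SimulationConfig,
) -> np.ndarray:
    defining = config.fate_defining_type[category]
    if defining is None:
        return np.full(size, founder, dtype=object)
    if size == 1:
        return np.array([defining], dtype=object)
    rest = np.where(
        rng.random(size - 2) < config.residual_progenitor_frac, founder, defining
    )
    return np.concatenate([[founder, defining], rest])


def _simulate_expression(
    rng: np.random.Generator, cell_types: np.ndarray, config: SimulationConfig
) -> ad.AnnData:
    """Negative-binomial counts with cell-type-specific marker elevation."""
    types = config.cell_types
    n_cells = len(cell_types)
    g = config.n_genes
    base_mean = np.exp(rng.normal(np.log(0.5), 1.0, size=g))
    # contiguous, non-overlapping marker blocks per type
    markers = {}
    for i, t in enumerate(types):
        lo = i * config.n_marker_genes_per_type
        hi = lo + config.n_marker_genes_per_type
        if hi > g:
            raise ValueError("n_genes too small for the requested marker blocks")
        markers[t] = np.arange(lo, hi)
    depth = np.exp(rng.normal(0.0, 0.3, size=n_cells))
    type_idx = {t: np.flatnonzero(cell_types == t) for t in types}
    mean = np.tile(base_mean, (n_cells, 1))
    for t, gidx in markers.items():
        cidx = type_idx[t]
        if len(cidx):
            mean[np.ix_(cidx, gidx)] *= np.exp(config.expression_effect_size)
    mean *= depth[:, None]
    size = config.dispersion
    counts = rng.negative_binomial(size, size / (size + mean))
    adata = ad.AnnData(X=sparse.csr_matrix(counts.astype(np.int64)))
    adata.var_names = [f"gene{i:04d}" for i in range(g)]
    adata.uns["marker_genes"] = {
        t: [f"gene{i:04d}" for i in idx] for t, idx in markers.items()
    }
    return adata


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate one barcoded experiment with full ground truth.

    Clones are founded per progenitor; each founder draws its integration
    barcodes with replacement from the library (so inter-clone collisions occur
    at the analytic birthday rate); every cell of a clone inherits the
    founder's barcode set; a cell emits triples only with probability
    ``barcode_recovery_rate``; per recovered cell-barcode pair the number of
    UMIs and per-triple read counts follow the configured distributions.
    """
    return _simulate(config, null=False)


def simulate_null(config: SimulationConfig) -> SimulatedExperiment:
    """Like :func:`simulate_experiment` but with clone/type association broken.

    Clone structure, barcodes and capture noise are generated identically;
    each cell's type is then redrawn i.i.d. from the pooled type frequencies,
    so any downstream clone-type coupling signal is null by construction.
    Clone fate categories in the truth table are set to ``"null"``.
    """
    return _simulate(config, null=True)


def _simulate(config: SimulationConfig, null: bool) -> SimulatedExperiment:
    rng = np.random.default_rng(config.seed)
    library_entropy = int(
        np.random.SeedSequence([config.seed, 0x1B]).generate_state(1)[0] // 2
    )

    subtypes = sorted(config.n_progenitors_per_subtype)
    founder_subtype = np.concatenate(
        [np.full(config.n_progenitors_per_subtype[s], s, dtype=object) for s in subtypes]
    )
    n_clones = len(founder_subtype)
    clone_ids = np.arange(1, n_clones + 1)

    # clone-level draws
    sizes = config.clone_size_dist.sample(n_clones, rng)
    categories = np.empty(n_clones, dtype=object)
    for s in subtypes:
        mask = founder_subtype == s
        cats = sorted(config.fate_profile[s])
        p = np.array([config.fate_profile[s][c] for c in cats])
        categories[mask] = rng.choice(cats, size=mask.sum(), p=p / p.sum())

    n_int = config.integrations_per_cell_dist.sample(n_clones, rng)
    barcode_sets = []
    for k in n_int:
        idx = np.sort(rng.integers(0, config.barcode_library_size, size=int(k)))
        barcode_sets.append(sorted(
            {_barcode_sequence(library_entropy, i, config.barcode_length) for i in idx}
        ))

    # cell-level draws
    n_cells = int(sizes.sum())
    cell_clone = np.repeat(clone_ids, sizes)
    cell_founder = np.repeat(founder_subtype, sizes)
    cell_types = np.empty(n_cells, dtype=object)
    pos = 0
    for ci in range(n_clones):
        s = int(sizes[ci])
        cell_types[pos:pos + s] = _sample_clone_types(
            rng, s, str(founder_subtype[ci]), str(categories[ci]), config
        )
        pos += s
    if null:
        drawn, counts = np.unique(cell_types.astype(str), return_counts=True)
        cell_types = rng.choice(drawn, size=n_cells, p=counts / counts.sum()).astype(object)
        categories = np.full(n_clones, "null", dtype=object)

    cell_bc = _random_seqs(rng, n_cells, 16)
    while len(set(cell_bc)) < n_cells:  # pragma: no cover - 16-mers rarely collide
        cell_bc = _random_seqs(rng, n_cells, 16)
    recovered = rng.random(n_cells) < config.barcode_recovery_rate

    # triple emission per recovered cell-barcode pair (vectorized draws)
    pair_cell, pair_bc = [], []
    for i in np.flatnonzero(recovered):
        for bc in barcode_sets[cell_clone[i] - 1]:
            pair_cell.append(i)
            pair_bc.append(bc)
    umi_counts = config.umi_per_pair_dist.sample(len(pair_cell), rng)
    total = int(umi_counts.sum())
    read_counts = config.reads_per_triple_dist.sample(total, rng)
    umis = _random_seqs(rng, total, 10)
    offsets = np.concatenate([[0], np.cumsum(umi_counts)])
    for p in range(len(pair_cell)):  # UMIs must be distinct within a pair
        lo, hi = offsets[p], offsets[p + 1]
        while len(set(umis[lo:hi])) < hi - lo:
            umis[lo:hi] = _random_seqs(rng, hi - lo, 10)
    triples = pd.DataFrame(
        {
            "cell_bc": np.repeat(cell_bc[pair_cell], umi_counts),
            "umi": umis,
            "lineage_bc": np.repeat(np.array(pair_bc, dtype=object), umi_counts),
            "reads": read_counts,
        }
    )
    triples = triples.sort_values(
        ["cell_bc", "lineage_bc", "umi"], kind="mergesort"
    ).reset_index(drop=True)

    annotations = pd.DataFrame(
        {
            "cell_id": cell_bc,
            "cell_type": cell_types.astype(str),
            "subtype": cell_types.astype(str),
            "timepoint": config.timepoint,
            "dataset": config.dataset,
        }
    )
    truth_cells = pd.DataFrame(
        {
            "cell_id": cell_bc,
            "clone_id": cell_clone,
            "founder_subtype": cell_founder.astype(str),
            "cell_type": cell_types.astype(str),
            "timepoint": config.timepoint,
            "recovered": recovered,
        }
    )
    truth_clones = pd.DataFrame(
        {
            "clone_id": clone_ids,
            "founder_subtype": founder_subtype.astype(str),
            "fate_category": categories.astype(str),
            "size": sizes,
            "barcodes": [";".join(b) for b in barcode_sets],
        }
    )

    adata = _simulate_expression(rng, cell_types.astype(str), config)
    adata.obs_names = cell_bc
    adata.obs["cell_type"] = cell_types.astype(str)
    adata.obs["subtype"] = cell_types.astype(str)
    adata.obs["timepoint"] = config.timepoint
    adata.obs["dataset"] = config.dataset

    return SimulatedExperiment(
        triples=triples,
        annotations=annotations,
        adata=adata,
        truth=SimTruth(cells=truth_cells, clones=truth_clones),
        config=config,
    )


# ---------------------------------------------------------------------------
# writers

def write_experiment(sim: SimulatedExperiment, outdir: str | Path) -> dict:
    """Write all simulator tables to ``outdir``; returns path map.

    Triples go to TSV; annotations and truth to CSV; expression to MTX
    (genes x cells) with row/column name files; the full config to a JSON
    manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "triples": outdir / "triples.tsv",
        "annotations": outdir / "annotations.csv",
        "truth_cells": outdir / "truth_cells.csv",
        "truth_clones": outdir / "truth_clones.csv",
        "expression_mtx": outdir / "expression.mtx",
        "expression_genes": outdir / "expression.genes.txt",
        "expression_cells": outdir / "expression.cells.txt",
        "config": outdir / "sim_config.json",
    }
    sim.triples.to_csv(paths["triples"], sep="\t", index=False)
    sim.annotations.to_csv(paths["annotations"], index=False)
    sim.truth.cells.to_csv(paths["truth_cells"], index=False)
    sim.truth.clones.to_csv(paths["truth_clones"], index=False)
    from scipy.io import mmwrite

    mmwrite(str(paths["expression_mtx"]), sparse.csr_matrix(sim.adata.X).T)
    paths["expression_genes"].write_text("\n".join(sim.adata.var_names) + "\n")
    paths["expression_cells"].write_text("\n".join(sim.adata.obs_names) + "\n")
    paths["config"].write_text(json.dumps(sim.config.to_dict(), indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}


def null_calibration_config(seed: int = 0, founders_per_subtype: int = 334,
                            **overrides) -> SimulationConfig:
    """Configuration for permutation-null calibration experiments.

    Three progenitor subtypes with fate profiles chosen so that all six cell
    types occur at comparable (>~10%) frequency, giving every state pair a
    non-degenerate shared-clone count.  Calibration of the permutation z-score
    (mean ~0, variance ~1, ~5% exceeding |1.96|) is a large-count property;
    with rare states the null counts are small integers and the z-score is
    too discrete for those checks to be meaningful.
    """
    profiles = {
        "RGC_1": {"neuron_linked": 0.5, "olig2_lineage": 0.25,
                  "s100a11_lineage": 0.25, "self_renewing": 0.0},
        "RGC_2": {"neuron_linked": 0.25, "olig2_lineage": 0.25,
                  "s100a11_lineage": 0.25, "self_renewing": 0.25},
        "RGC_3": {"neuron_linked": 0.2, "olig2_lineage": 0.4,
                  "s100a11_lineage": 0.4, "self_renewing": 0.0},
    }
    kwargs = dict(
        n_progenitors_per_subtype={s: founders_per_subtype for s in profiles},
        fate_profile=profiles,
        n_genes=20,
        n_marker_genes_per_type=3,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


DEFAULT_FLANK5 = "CTGACTCGAG"
DEFAULT_FLANK3 = "AGCTGTCGAC"


def write_fastq(
    sim: SimulatedExperiment,
    path: str | Path,
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
) -> int:
    """Emit read-2-style FASTQ for the extraction path; returns read count.

    Each triple becomes ``reads`` identical records whose sequence is
    ``flank5 + lineage_bc + flank3`` and whose name carries the cell barcode
    and UMI (``read<k>:<cell_bc>:<umi>``), mirroring pipelines that stash
    Cell/UMI in read names before barcode extraction.  ``.gz`` paths are
    written gzip-compressed.
    """
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    k = 0
    with opener(path, "wt") as fh:
        for t in sim.triples.itertuples(index=False):
            seq = f"{flank5}{t.lineage_bc}{flank3}"
            qual = "I" * len(seq)
            for _ in range(int(t.reads)):
                fh.write(f"@read{k}:{t.cell_bc}:{t.umi}\n{seq}\n+\n{qual}\n")
                k += 1
    return k
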