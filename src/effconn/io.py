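"""File formats and run configuration.

Cohorts live on disk in three interchangeable layouts:

* a directory of per-subject CSVs (rows = labelled regions, columns =
  timepoints), optionally with per-subject ground-truth edge lists and a
  JSON manifest;
* a single compressed ``.npz`` bundle holding the data cube and truths;
* the netsim benchmark ``.mat`` dialect — subjects stacked along time in a
  ``ts`` array with per-subject networks in ``net``.

Graphs are written as labelled adjacency CSVs and (source, target, weight)
edge-list TSVs; configuration round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import loadmat

from .data import CohortTimeSeries
from .model import DecoderConfig, ECModel, EncoderConfig, ModelState
from .simulate import GroundTruthGraph, SimOptions
from .training import TrainingConfig

__all__ = [
    "SimulateSpec",
    "RunConfig",
    "load_cohort",
    "save_cohort_csv_dir",
    "save_cohort_bundle",
    "save_adjacency_csv",
    "load_adjacency_csv",
    "save_edge_list",
    "load_edge_list",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# cohorts


def _validate_matrix(values: np.ndarray, subject: str, regions: list[str]) -> None:
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, t = bad[0]
        raise ValueError(
            f"invalid value for subject {subject!r}, region {regions[int(i)]!r} "
            f"at timepoint {int(t)}"
        )


def save_cohort_csv_dir(
    cohort: CohortTimeSeries,
    directory: str | Path,
    truths: list[GroundTruthGraph] | None = None,
    manifest_extra: dict | None = None,
) -> Path:
    """One CSV per subject plus truth edge lists and a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    columns = [f"t{t:04d}" for t in range(cohort.n_timepoints)]
    for s, sid in enumerate(cohort.subject_ids):
        df = pd.DataFrame(cohort.subject(s), index=cohort.region_labels, columns=columns)
        df.to_csv(directory / f"{sid}.csv", index_label="region")
        if truths is not None:
            arcs = pd.DataFrame(truths[s].arc_list, columns=["source", "target"])
            arcs.to_csv(directory / f"{sid}_truth.tsv", sep="\t", index=False)
    manifest = {
        "n_subjects": cohort.n_subjects,
        "n_regions": cohort.n_regions,
        "n_timepoints": cohort.n_timepoints,
        "subject_ids": cohort.subject_ids,
        "region_labels": cohort.region_labels,
    }
    manifest.update(manifest_extra or {})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def save_cohort_bundle(
    cohort: CohortTimeSeries,
    path: str | Path,
    truths: list[GroundTruthGraph] | None = None,
) -> Path:
    """Single compressed array bundle with data (+ truth adjacencies)."""
    path = Path(path)
    arrays = {
        "data": cohort.data,
        "subject_ids": np.array(cohort.subject_ids),
        "region_labels": np.array(cohort.region_labels),
    }
    if truths is not None:
        arrays["truths"] = np.stack([g.adjacency for g in truths])
    np.savez_compressed(path, **arrays)
    return path


def _load_csv_dir(directory: Path) -> tuple[CohortTimeSeries, list[GroundTruthGraph] | None]:
    files = sorted(p for p in directory.glob("*.csv"))
    if not files:
        raise ValueError(f"unrecognized cohort layout: no CSV files in {directory}")
    mats, sids, regions, shapes = [], [], None, set()
    for f in files:
        df = pd.read_csv(f, index_col=0)
        labels = [str(r) for r in df.index]
        if regions is None:
            regions = labels
        elif labels != regions:
            raise ValueError(f"subject file {f.name} has mismatched region labels")
        values = df.to_numpy(dtype=np.float64, na_value=np.nan)
        _validate_matrix(values, f.stem, labels)
        shapes.add(values.shape)
        mats.append(values)
        sids.append(f.stem)
    if len(shapes) != 1:
        raise ValueError(f"ragged cohort: subject matrices have shapes {sorted(shapes)}")
    cohort = CohortTimeSeries(np.stack(mats), sids, regions)
    truths = None
    truth_files = [directory / f"{sid}_truth.tsv" for sid in sids]
    if all(f.exists() for f in truth_files):
        n = cohort.n_regions
        truths = []
        for f in truth_files:
            adj = np.zeros((n, n), dtype=np.int64)
            edges = pd.read_csv(f, sep="\t")
            for _, row in edges.iterrows():
                adj[int(row["source"]), int(row["target"])] = 1
            truths.append(GroundTruthGraph(adj))
    return cohort, truths


def _load_bundle(path: Path) -> tuple[CohortTimeSeries, list[GroundTruthGraph] | None]:
    with np.load(path, allow_pickle=False) as z:
        data = np.asarray(z["data"], dtype=np.float64)
        sids = [str(s) for s in z["subject_ids"]] if "subject_ids" in z else []
        regions = [str(r) for r in z["region_labels"]] if "region_labels" in z else []
        truths = (
            [GroundTruthGraph(a) for a in z["truths"]] if "truths" in z else None
        )
    for s, mat in enumerate(data):
        _validate_matrix(
            mat,
            sids[s] if sids else f"sub-{s + 1:03d}",
            regions or [f"roi-{i + 1}" for i in range(mat.shape[0])],
        )
    return CohortTimeSeries(data, sids, regions), truths


def _load_netsim(path: Path) -> tuple[CohortTimeSeries, list[GroundTruthGraph] | None]:
    """netsim dialect: ts is (subjects * timepoints, nodes), stacked in time."""
    mat = loadmat(path)
    if "ts" not in mat:
        raise ValueError(f"unrecognized cohort layout: no 'ts' array in {path.name}")
    ts = np.asarray(mat["ts"], dtype=np.float64)
    n_tp = int(np.ravel(mat["Ntimepoints"])[0]) if "Ntimepoints" in mat else None
    n_sub = int(np.ravel(mat["Nsubjects"])[0]) if "Nsubjects" in mat else None
    if n_tp is None and n_sub is None:
        raise ValueError("netsim file must declare Ntimepoints or Nsubjects")
    if n_tp is None:
        n_tp = ts.shape[0] // n_sub
    if n_sub is None:
        n_sub = ts.shape[0] // n_tp
    if n_sub * n_tp != ts.shape[0]:
        raise ValueError(
            f"ragged cohort: {ts.shape[0]} stacked rows do not split into "
            f"{n_sub} subjects x {n_tp} timepoints"
        )
    n_nodes = ts.shape[1]
    data = ts.reshape(n_sub, n_tp, n_nodes).transpose(0, 2, 1)
    regions = [f"roi-{i + 1}" for i in range(n_nodes)]
    for s, m in enumerate(data):
        _validate_matrix(m, f"sub-{s + 1:03d}", regions)
    truths = None
    if "net" in mat:
        net = np.asarray(mat["net"], dtype=np.float64)
        if net.ndim == 2:
            net = np.broadcast_to(net, (n_sub,) + net.shape)
        truths = []
        for a in net:
            adj = (a > 0).astype(np.int64)
            np.fill_diagonal(adj, 0)
            truths.append(GroundTruthGraph(adj))
    return CohortTimeSeries(data, region_labels=regions), truths


def load_cohort(
    path: str | Path, normalize: bool = True
) -> tuple[CohortTimeSeries, list[GroundTruthGraph] | None]:
    """Load a cohort from any recognized layout.

    Returns (cohort, truths-or-None).  With ``normalize=True`` (default)
    each subject's regions are z-scored over time.
    """
    path = Path(path)
    if path.is_dir():
        cohort, truths = _load_csv_dir(path)
    elif path.suffix == ".npz":
        cohort, truths = _load_bundle(path)
    elif path.suffix == ".mat":
        cohort, truths = _load_netsim(path)
    else:
        raise ValueError(f"unrecognized cohort layout: {path}")
    if normalize:
        cohort = cohort.zscore()
    return cohort, truths


# ---------------------------------------------------------------------------
# graphs


def save_adjacency_csv(
    matrix: np.ndarray, path: str | Path, labels: list[str] | None = None
) -> Path:
    matrix = np.asarray(matrix)
    labels = labels or [f"roi-{i + 1}" for i in range(matrix.shape[0])]
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        Path(path), index_label="region"
    )
    return Path(path)


def load_adjacency_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.float64), [str(i) for i in df.index]


def save_edge_list(
    matrix: np.ndarray, path: str | Path, labels: list[str] | None = None
) -> Path:
    """TSV of (source_label, target_label, weight) for nonzero entries."""
    matrix = np.asarray(matrix)
    labels = labels or [f"roi-{i + 1}" for i in range(matrix.shape[0])]
    rows = [
        (labels[i], labels[j], matrix[i, j])
        for i, j in np.argwhere(matrix != 0)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        Path(path), sep="\t", index=False
    )
    return Path(path)


def load_edge_list(path: str | Path, labels: list[str]) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    matrix = np.zeros((len(labels), len(labels)))
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        matrix[index[str(row["source"])], index[str(row["target"])]] = row["weight"]
    return matrix


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(state: ModelState, path: str | Path) -> Path:
    """Parameter arrays plus library-agnostic JSON metadata in one archive."""
    path = Path(path)
    params = state.model.parameters()
    meta = {
        "n_timepoints": state.model.n_timepoints,
        "n_regions": state.n_regions,
        "seed": state.seed,
        "model_seed": state.model.seed,
        "encoder_config": dataclasses.asdict(state.encoder_config),
        "decoder_config": dataclasses.asdict(state.decoder_config),
        "training_config": state.training_config,
        "param_shapes": [list(p.shape) for p in params],
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(params)}
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez_compressed(path, **arrays)
    return path


def load_checkpoint(path: str | Path) -> ModelState:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"]))
        model = ECModel(
            meta["n_timepoints"],
            EncoderConfig(**meta["encoder_config"]),
            DecoderConfig(**meta["decoder_config"]),
            seed=meta["model_seed"],
        )
        params = model.parameters()
        if len(params) != len(meta["param_shapes"]):
            raise ValueError("checkpoint does not match the reconstructed model")
        for i, p in enumerate(params):
            p.data = np.asarray(z[f"param_{i}"], dtype=np.float64)
    return ModelState(
        model=model,
        seed=meta["seed"],
        training_config=meta["training_config"],
        n_regions=meta.get("n_regions"),
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class SimulateSpec:
    """What cohort to generate when no data path is given."""

    n_nodes: int = 5
    n_arcs: int = 5
    n_bidirectional: int = 0
    n_subjects: int = 5
    n_timepoints: int = 200


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML."""

    seed: int = 0
    data_path: str | None = None
    normalize: bool = True
    guidance: str = "matmul"  # matmul | hadamard | off
    encoder_preset: str = "small"  # small | default
    simulate: SimulateSpec = field(default_factory=SimulateSpec)
    sim_options: SimOptions = field(default_factory=SimOptions)
    encoder: EncoderConfig | None = None
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self):
        if self.guidance not in ("matmul", "hadamard", "off"):
            raise ValueError("guidance must be matmul, hadamard or off")
        if self.encoder is None:
            self.encoder = (
                EncoderConfig.small() if self.encoder_preset == "small" else EncoderConfig()
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("simulate", SimulateSpec),
            ("sim_options", SimOptions),
            ("encoder", EncoderConfig),
            ("decoder", DecoderConfig),
            ("training", TrainingConfig),
        ):
            if isinstance(d.get(key), dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
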