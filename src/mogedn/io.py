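"""Readers, writers, cohort alignment and checkpoint bundles.

Matrix files are TSV or CSV (gzip transparent): first column sample ID,
header row feature IDs, samples as rows.  Labels are a two-column table
(sample_id, subtype).  Checkpoint bundles are directories holding a
schema-versioned JSON manifest plus one npz of parameter arrays, so partial
reloads (e.g. encoders only) stay straightforward.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MogednModel
from .nn import clone_state, load_state
from .preprocess import OmicsView
from .train_phases import PretrainResult, TrainConfig

__all__ = ["read_omics_table", "write_omics_table", "read_labels",
           "align_cohort", "AlignedCohort",
           "save_pretrain_bundle", "load_pretrain_bundle"]

BUNDLE_SCHEMA = 1


def _detect_sep(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    return "," if name.endswith(".csv") else "\t"


def read_omics_table(path, modality_id: str) -> OmicsView:
    """Parse a sample x feature table into an OmicsView."""
    path = Path(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dupes[:5]}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row_label = df.index[coerced.isna().argmax()]
            row_no = int(np.flatnonzero(df.index == row_label)[0]) + 2
            raise ValueError(
                f"{path}: non-numeric cell in column {col!r} at file row "
                f"{row_no}")
    matrix = df.to_numpy(dtype=float)
    if np.isnan(matrix).any():
        i, j = np.argwhere(np.isnan(matrix))[0]
        raise ValueError(f"{path}: missing value at file row {i + 2}, "
                         f"column {df.columns[j]!r}")
    return OmicsView(modality_id=modality_id, matrix=matrix,
                     feature_names=[str(c) for c in df.columns],
                     sample_ids=[str(s) for s in df.index])


def write_omics_table(view: OmicsView, path) -> None:
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.DataFrame(view.matrix, index=view.sample_ids,
                      columns=view.feature_names)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_labels(path) -> pd.Series:
    """Two-column table sample_id, subtype."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, subtype)")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str))
    if s.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample IDs in labels")
    return s


@dataclass
class AlignedCohort:
    views: dict[str, OmicsView]
    labels: np.ndarray
    label_names: list[str]
    sample_ids: list[str]
    dropped: dict[str, int]


def align_cohort(views: dict[str, OmicsView], labels: pd.Series) -> AlignedCohort:
    """Strict intersection of sample IDs across all modalities and labels;
    output order is the sorted intersection regardless of input order."""
    common = set(labels.index)
    for v in views.values():
        common &= set(v.sample_ids)
    if not common:
        raise ValueError("no samples shared by all modalities and labels")
    order = sorted(common)
    dropped = {m: v.n_samples - len(order) for m, v in views.items()}
    dropped["labels"] = len(labels) - len(order)
    aligned = {}
    for m, v in views.items():
        pos = {s: i for i, s in enumerate(v.sample_ids)}
        idx = [pos[s] for s in order]
        aligned[m] = OmicsView(modality_id=v.modality_id,
                               matrix=v.matrix[idx],
                               feature_names=v.feature_names,
                               sample_ids=order,
                               normalized=v.normalized)
    label_names = sorted(pd.unique(labels.loc[order]).tolist())
    to_int = {l: i for i, l in enumerate(label_names)}
    y = np.array([to_int[labels.loc[s]] for s in order], dtype=int)
    return AlignedCohort(views=aligned, labels=y, label_names=label_names,
                         sample_ids=order, dropped=dropped)


# -- checkpoint bundles ------------------------------------------------------

def save_pretrain_bundle(result: PretrainResult, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    shared = result.shared_model
    manifest = {
        "schema_version": BUNDLE_SCHEMA,
        "modalities": shared.modalities,
        "in_dims": {m: shared.encoders[m].in_dim for m in shared.modalities},
        "cohorts": {name: {"n_classes": mdl.n_classes}
                    for name, mdl in result.models.items()},
        "config": asdict(result.config),
        "seed": result.config.seed,
    }
    arrays: dict[str, np.ndarray] = {}
    for k, v in clone_state(shared.encoder_params()).items():
        arrays[f"shared/{k}"] = v
    for k, v in clone_state(shared.decoder_params()).items():
        arrays[f"shared/{k}"] = v
    for k, v in shared.decoder.buffers().items():
        arrays[f"buffer/{k}"] = v.copy()
    for name, mdl in result.models.items():
        state = clone_state({**mdl.head_params(), **mdl.fusion_params()})
        for k, v in state.items():
            arrays[f"cohort/{name}/{k}"] = v
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savez(path / "arrays.npz", **arrays)
    with open(path / "history.json", "w") as fh:
        json.dump(result.histories, fh, indent=2, default=str)


def load_pretrain_bundle(path) -> PretrainResult:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest["schema_version"] != BUNDLE_SCHEMA:
        raise ValueError(f"unsupported bundle schema "
                         f"{manifest['schema_version']}")
    arrays = dict(np.load(path / "arrays.npz"))
    config = TrainConfig(**manifest["config"])
    rng = np.random.default_rng(0)  # shapes only; weights overwritten below
    in_dims = {m: int(d) for m, d in manifest["in_dims"].items()}
    models: dict[str, MogednModel] = {}
    first = None
    for name, info in manifest["cohorts"].items():
        mdl = MogednModel.build(in_dims, int(info["n_classes"]), rng)
        if first is None:
            first = mdl
        else:
            mdl.encoders = first.encoders
            mdl.decoder = first.decoder
        shared_state = {k[len("shared/"):]: v for k, v in arrays.items()
                        if k.startswith("shared/")}
        load_state({**mdl.encoder_params(), **mdl.decoder_params()},
                   shared_state)
        buf = {k[len("buffer/"):]: v for k, v in arrays.items()
               if k.startswith("buffer/")}
        if buf:
            mdl.decoder.load_buffers(buf)
        prefix = f"cohort/{name}/"
        cohort_state = {k[len(prefix):]: v for k, v in arrays.items()
                        if k.startswith(prefix)}
        load_state({**mdl.head_params(), **mdl.fusion_params()}, cohort_state)
        models[name] = mdl
    histories = {}
    hist_path = path / "history.json"
    if hist_path.exists():
        histories = json.loads(hist_path.read_text())
    return PretrainResult(models=models, config=config, histories=histories)
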