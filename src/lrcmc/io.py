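"""File I/O: view matrices, result files and the run manifest.

Views are read from delimited text (CSV/TSV) or MatrixMarket files in either
orientation (samples as rows, the common layout of tabular omics exports, or
samples as columns, the solver's internal convention) and are always stored
internally as features-by-samples.  Results are written as plain text:
labels as two-column TSV, metrics and the manifest as JSON, the consensus
graph as a sparse MatrixMarket file of its above-threshold entries.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .graph import AffinityGraph, ViewData
from .metrics import MetricReport
from .solver import ClusterLabels, SolverState

__all__ = ["ParseError", "RunManifest", "read_view", "read_labels",
           "check_alignment", "write_view", "write_results"]

ORIENTATIONS = ("samples_as_rows", "samples_as_cols")


class ParseError(ValueError):
    """Malformed input file (ragged rows, non-numeric cells, bad ids)."""


@dataclass
class RunManifest:
    """Everything needed to reproduce a run."""

    config: dict
    inputs: list[dict] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    final_beta: float = 0.0
    component_count: int = 0
    elapsed_seconds: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_view(
    path: str | Path,
    orientation: str = "samples_as_rows",
    delimiter: str | None = None,
    header: bool = False,
    ids: bool = False,
) -> ViewData:
    """Read one view into the internal features-by-samples layout.

    ``orientation`` says how samples are laid out in the *file*; ``header``
    / ``ids`` declare an identifier row/column (along the sample axis) to
    use as sample ids.  MatrixMarket files (``.mtx``) are densified.
    """
    path = Path(path)
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    sample_ids: list[str] | None = None
    if path.suffix.lower() in (".mtx", ".mm"):
        mat = scipy.io.mmread(path)
        arr = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
    else:
        sep = _detect_delimiter(path, delimiter)
        want_header = header and orientation == "samples_as_cols"
        want_index = ids and orientation == "samples_as_rows"
        try:
            df = pd.read_csv(
                path,
                sep=sep,
                header=0 if want_header else None,
                index_col=0 if want_index else None,
            )
        except (pd.errors.ParserError, ValueError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
        bad = df.map(lambda x: isinstance(x, str)).to_numpy()
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ParseError(
                f"{path}: non-numeric cell at row {r + 1}, column {c + 1}"
            )
        if df.isna().to_numpy().any():
            count = int(df.isna().to_numpy().sum())
            raise ParseError(f"{path}: {count} missing value(s); not permitted")
        if want_header:
            sample_ids = [str(x) for x in df.columns]
        if want_index:
            sample_ids = [str(x) for x in df.index]
        arr = df.to_numpy(dtype=float)
    if orientation == "samples_as_rows":
        arr = arr.T
    return ViewData(matrix=arr, sample_ids=sample_ids)


def check_alignment(views: list[ViewData]) -> None:
    """Fail with the offending views if sample ids disagree across views."""
    if not views:
        return
    ref = views[0].sample_ids
    offenders = [
        i for i, v in enumerate(views[1:], start=1) if v.sample_ids != ref
    ]
    if offenders:
        raise ParseError(
            f"sample ids of view(s) {offenders} do not match view 0"
        )


def write_view(
    view: ViewData,
    path: str | Path,
    orientation: str = "samples_as_rows",
    delimiter: str = ",",
) -> None:
    """Write a view back to delimited text (inverse of :func:`read_view`)."""
    arr = view.matrix
    if orientation == "samples_as_rows":
        arr = arr.T
    np.savetxt(path, arr, delimiter=delimiter, fmt="%.10g")


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a two-column (sample_id, cluster) TSV written by
    :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", header=0)
    return [str(x) for x in df.iloc[:, 0]], df.iloc[:, 1].to_numpy()


def write_results(
    outdir: str | Path,
    labels: ClusterLabels,
    sample_ids: list[str],
    manifest: RunManifest,
    z: AffinityGraph,
    state: SolverState | None = None,
    report: MetricReport | None = None,
    support_tol: float = 1e-8,
) -> dict[str, Path]:
    """Write labels (TSV), metrics + manifest (JSON), consensus (MatrixMarket)
    and the per-iteration log; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["labels"] = outdir / "labels.tsv"
    with open(paths["labels"], "w") as fh:
        fh.write("sample_id\tcluster\n")
        for sid, lab in zip(sample_ids, labels.labels):
            fh.write(f"{sid}\t{int(lab)}\n")

    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(manifest.to_json() + "\n")

    if report is not None:
        paths["metrics"] = outdir / "metrics.json"
        paths["metrics"].write_text(json.dumps(report.to_dict(), indent=2) + "\n")

    sym = z.weights
    keep = sp.coo_matrix(np.where(sym > support_tol, sym, 0.0))
    paths["consensus"] = outdir / "consensus.mtx"
    scipy.io.mmwrite(paths["consensus"], keep)

    if state is not None:
        paths["log"] = outdir / "run.log"
        with open(paths["log"], "w") as fh:
            fh.write("iteration\tbeta\tcomponents\tobjective\n")
            for i, (b, comp, obj) in enumerate(
                zip(state.beta_trace, state.component_trace,
                    state.objective_trace),
                start=1,
            ):
                fh.write(f"{i}\t{b:.6g}\t{comp}\t{obj:.10g}\n")
    return paths


def make_manifest(
    config: dict, input_paths: list[str | Path], started: float
) -> RunManifest:
    inputs = [
        {"path": str(p), "sha256": file_checksum(p)} for p in input_paths
    ]
    return RunManifest(
        config=config, inputs=inputs, elapsed_seconds=time.time() - started
    )
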