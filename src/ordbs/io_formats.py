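"""Readers and writers for models, expression data, and analysis artifacts.

File formats (all UTF-8, tab-delimited, header row mandatory; floats written in
shortest round-tripping decimal form so writes are deterministic and lossless):

* expression TSV — header = node labels, one row per experiment;
* intervention TSV — columns ``experiment`` and ``interventions``, the latter
  a semicolon-separated list of ``label=value`` tokens (empty field means an
  observational experiment);
* model JSON — ``labels``, ``weights`` (edge list of [source, target,
  weight]), ``means``, ``sigmas``, ``gen_order`` (all label-based).

Node labels are strings throughout the file layer; integer column indices
are an internal detail of the in-memory containers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dag_model import CausalDAG, ExperimentSet
from .exceptions import FormatError, ModelError
from .likelihood import MLEResult
from .sampling import SampleSet

__all__ = [
    "DatasetBundle",
    "read_dataset",
    "write_dataset",
    "read_model",
    "write_model",
    "write_mle_result",
    "write_pair_preferences",
    "write_triplet_preferences",
    "write_sample_set",
]

def _fmt(x: float) -> str:
    # shortest round-tripping decimal form: deterministic and lossless
    return repr(float(x))


@dataclass(frozen=True)
class DatasetBundle:
    """An experiment set plus its node labels and file provenance."""

    experiments: ExperimentSet
    labels: tuple[str, ...]
    source: str = ""
    checksum: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != self.experiments.p:
            raise FormatError("label count must match matrix width")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def read_dataset(
    expression_path: str | Path,
    intervention_path: str | Path | None = None,
    *,
    genes: Sequence[str] | None = None,
) -> DatasetBundle:
    """Load an expression TSV and optional intervention TSV into a validated bundle.

    ``genes`` restricts the columns (in the given order); interventions on
    dropped genes are discarded from the annotation.
    """
    expression_path = Path(expression_path)
    try:
        df = pd.read_csv(
            expression_path, sep="\t", header=0, dtype=float, float_precision="round_trip"
        )
    except ValueError as exc:
        raise FormatError(f"{expression_path}: non-numeric or ragged data ({exc})") from exc
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise FormatError(f"{expression_path}: missing value near line {row}")
    labels = tuple(str(c) for c in df.columns)
    pos = {lab: a for a, lab in enumerate(labels)}
    interventions: list[dict[int, float]] = [{} for _ in range(len(df))]
    if intervention_path is not None:
        intervention_path = Path(intervention_path)
        idf = pd.read_csv(intervention_path, sep="\t", header=0, dtype=str).fillna("")
        if list(idf.columns[:2]) != ["experiment", "interventions"]:
            raise FormatError(f"{intervention_path}: expected columns experiment, interventions")
        if len(idf) != len(df):
            raise FormatError(
                f"{intervention_path}: {len(idf)} rows for {len(df)} experiments"
            )
        for line, (k_str, tokens) in enumerate(zip(idf["experiment"], idf["interventions"]), start=2):
            k = int(k_str)
            if not 0 <= k < len(df):
                raise FormatError(f"{intervention_path}:{line}: experiment index {k} out of range")
            if not tokens:
                continue
            for tok in str(tokens).split(";"):
                if "=" not in tok:
                    raise FormatError(f"{intervention_path}:{line}: malformed token {tok!r}")
                lab, val = tok.split("=", 1)
                if lab not in pos:
                    raise FormatError(f"{intervention_path}:{line}: unknown node label {lab!r}")
                interventions[k][pos[lab]] = float(val)
    data = ExperimentSet(X=df.to_numpy(), interventions=tuple(interventions))
    if genes is not None:
        missing = [g for g in genes if g not in pos]
        if missing:
            raise FormatError(f"unknown gene labels requested: {missing}")
        data = data.subset([pos[g] for g in genes])
        labels = tuple(genes)
    return DatasetBundle(
        experiments=data,
        labels=labels,
        source=str(expression_path),
        checksum=_sha256(expression_path),
    )


def write_dataset(
    bundle_or_data: DatasetBundle | ExperimentSet,
    expression_path: str | Path,
    intervention_path: str | Path | None = None,
    *,
    labels: Sequence[str] | None = None,
) -> None:
    """Write an experiment set to the expression/intervention TSV pair."""
    if isinstance(bundle_or_data, DatasetBundle):
        data, labels = bundle_or_data.experiments, bundle_or_data.labels
    else:
        data = bundle_or_data
        labels = tuple(labels) if labels else tuple(f"n{i}" for i in range(data.p))
    lines = ["\t".join(labels)]
    for row in data.X:
        lines.append("\t".join(_fmt(v) for v in row))
    Path(expression_path).write_text("\n".join(lines) + "\n")
    if intervention_path is not None:
        ilines = ["experiment\tinterventions"]
        for k, J in enumerate(data.interventions):
            toks = ";".join(f"{labels[j]}={_fmt(v)}" for j, v in sorted(J.items()))
            ilines.append(f"{k}\t{toks}")
        Path(intervention_path).write_text("\n".join(ilines) + "\n")


def write_model(dag: CausalDAG, path: str | Path) -> None:
    """Serialize a model to JSON (label-based edge list; deterministic bytes)."""
    sources, targets = np.nonzero(dag.W)
    payload = {
        "labels": list(dag.labels),
        "weights": [
            [dag.labels[i], dag.labels[j], float(dag.W[i, j])]
            for i, j in sorted(zip(sources.tolist(), targets.tolist()))
        ],
        "means": [float(v) for v in dag.m],
        "sigmas": [float(v) for v in dag.sigma],
        "gen_order": [dag.labels[i] for i in dag.gen_order],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_model(path: str | Path) -> CausalDAG:
    """Load a model JSON; rejects cyclic edge lists via the acyclicity check."""
    payload = json.loads(Path(path).read_text())
    try:
        labels = [str(v) for v in payload["labels"]]
        pos = {lab: a for a, lab in enumerate(labels)}
        p = len(labels)
        W = np.zeros((p, p))
        for src, tgt, w in payload["weights"]:
            W[pos[src], pos[tgt]] = float(w)
        m = np.asarray(payload["means"], dtype=float)
        sigma = np.asarray(payload["sigmas"], dtype=float)
        order = np.array([pos[lab] for lab in payload["gen_order"]], dtype=np.intp)
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed model file ({exc})") from exc
    try:
        return CausalDAG(W=W, m=m, sigma=sigma, gen_order=order, labels=tuple(labels))
    except ModelError as exc:
        raise ModelError(f"{path}: {exc}") from exc


def write_mle_result(
    result: MLEResult, prefix: str | Path, labels: Sequence[str] | None = None
) -> None:
    """Write an MLE fit: W_hat matrix TSV, per-node params TSV, scalar run record."""
    prefix = Path(prefix)
    p = result.W_hat.shape[0]
    labels = tuple(labels) if labels else tuple(f"n{i}" for i in range(p))
    lines = ["\t".join(("node",) + labels)]
    for i in range(p):
        lines.append("\t".join([labels[i]] + [_fmt(v) for v in result.W_hat[i]]))
    Path(f"{prefix}.W_hat.tsv").write_text("\n".join(lines) + "\n")
    plines = ["node\tm_hat\tsigma_hat"]
    for j in range(p):
        plines.append(f"{labels[j]}\t{_fmt(result.m_hat[j])}\t{_fmt(result.sigma_hat[j])}")
    Path(f"{prefix}.params.tsv").write_text("\n".join(plines) + "\n")
    record = {
        "ell_max": result.ell_max,
        "ordering": [labels[i] for i in result.ordering],
    }
    Path(f"{prefix}.json").write_text(json.dumps(record, indent=1, sort_keys=True) + "\n")


def write_pair_preferences(prefs, path: str | Path, labels: Sequence[str] | None = None) -> None:
    p = prefs.p
    labels = tuple(labels) if labels else tuple(f"n{i}" for i in range(p))
    lines = ["i\tj\tpi"]
    for i in range(p):
        for j in range(p):
            if i != j:
                lines.append(f"{labels[i]}\t{labels[j]}\t{_fmt(prefs.pi[i, j])}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_triplet_preferences(prefs, path: str | Path, labels: Sequence[str] | None = None) -> None:
    from itertools import combinations, permutations

    p = prefs.p
    labels = tuple(labels) if labels else tuple(f"n{i}" for i in range(p))
    header = ["i\tj\tk"] + ["rho_" + "".join(map(str, perm)) for perm in permutations(range(3))]
    lines = ["\t".join(header)]
    for tri in combinations(range(p), 3):
        row = [labels[tri[0]], labels[tri[1]], labels[tri[2]]]
        for perm in permutations(range(3)):
            row.append(_fmt(prefs.rho[tri[perm[0]], tri[perm[1]], tri[perm[2]]]))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_sample_set(samples: SampleSet, path: str | Path, labels: Sequence[str] | None = None) -> None:
    """Rank-ordered sample set: ordering, surrogate score, ell_max, weight."""
    if samples.orderings:
        p = len(samples.orderings[0])
        labels = tuple(labels) if labels else tuple(f"n{i}" for i in range(p))
    lines = ["rank\tordering\tsurrogate\tell_max\tweight"]
    for r, o in enumerate(samples.orderings):
        ell = samples.ell_max[r] if samples.ell_max is not None else float("nan")
        w = samples.weights[r] if samples.weights is not None else float("nan")
        lines.append(
            f"{r}\t{','.join(labels[i] for i in o)}\t{_fmt(samples.surrogate[r])}"
            f"\t{_fmt(ell)}\t{_fmt(w)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
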