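"""Delimited-text readers/writers, run manifests and the config format.

Matrices are sample-major: rows are individuals, columns are variables, with
a header row of variable names and an optional leading column of sample IDs.
Missing values are an input error — the model assumes complete data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InputError",
    "read_matrix",
    "inverse_rank_normal",
    "write_outputs",
    "RunManifest",
    "read_config",
]


class InputError(ValueError):
    """Malformed input file (distinct from numerical failure; CLI exit 1)."""


def _sniff_sep(path: Path) -> str:
    first = path.open().readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def read_matrix(path, role: str = "response", rank_normal: bool = False):
    """Read a delimited numeric matrix with header and optional sample IDs.

    Returns (matrix, column_labels, sample_ids). ``rank_normal`` applies the
    inverse rank-normal transform column-wise (responses only).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{role} file not found: {path}")
    sep = _sniff_sep(path)
    header = [h.strip() for h in path.open().readline().rstrip("\n").split(sep)]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise InputError(f"{role} file {path}: duplicated column labels {dupes}")
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise InputError(f"{role} file {path}: ragged or malformed rows ({exc})") from exc
    sample_ids = None
    first = df.columns[0]
    if df[first].dtype == object:
        sample_ids = df[first].astype(str).tolist()
        df = df.drop(columns=[first])
    labels = [str(c) for c in df.columns]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise InputError(f"{role} file {path}: duplicated column labels {sorted(dupes)}")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise InputError(f"{role} file {path}: non-numeric column(s) {bad}")
    mat = df.to_numpy(dtype=float)
    if np.isnan(mat).any():
        rows, cols = np.nonzero(np.isnan(mat))
        raise InputError(
            f"{role} file {path}: missing value at row {rows[0] + 2}, "
            f"column {labels[cols[0]]!r} (values must be complete)")
    if rank_normal:
        mat = np.column_stack([inverse_rank_normal(mat[:, j]) for j in range(mat.shape[1])])
    return mat, labels, sample_ids


def inverse_rank_normal(x: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom-type inverse rank-normal transform: Φ^{-1}((r − c)/(n − 2c + 1)).

    Ties get average ranks; the default offset c = 3/8 is the classical Blom
    constant.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))


@dataclass
class RunManifest:
    """Provenance of a run: inputs, config, seed, timing, acceptance rates."""

    input_hashes: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0
    software_version: str = ""
    started: str = ""
    finished: str = ""
    acceptance_rates: dict = field(default_factory=dict)

    @staticmethod
    def hash_file(path) -> str:
        h = hashlib.sha256()
        h.update(Path(path).read_bytes())
        return h.hexdigest()

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def write_outputs(summary, out_dir, manifest: RunManifest | None = None,
                  force: bool = False):
    """Write the posterior summary file set into ``out_dir``.

    Emits mpip.csv (s×p), mepip.csv (s×s), associations.tsv, edges.tsv and
    hotspots.tsv with 1-based/header labels, plus manifest.json. Floats use
    the shortest round-trip representation, so values reload exactly.
    Refuses a non-empty target directory unless ``force``.
    """
    from .summaries import threshold_network

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise InputError(f"output directory {out} is not empty (use force/--force)")
    out.mkdir(parents=True, exist_ok=True)
    s, p = summary.mpip.shape
    rnames = summary.response_names or [f"response_{k+1}" for k in range(s)]
    pnames = summary.predictor_names or [f"predictor_{j+1}" for j in range(p)]
    pd.DataFrame(summary.mpip, index=rnames, columns=pnames).to_csv(out / "mpip.csv")
    pd.DataFrame(summary.mepip, index=rnames, columns=rnames).to_csv(out / "mepip.csv")
    assoc, edges = threshold_network(summary)
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    pd.DataFrame({"predictor": pnames, "E_pi": summary.pi_mean}).to_csv(
        out / "hotspots.tsv", sep="\t", index=False)
    if not summary.diagnostics.empty:
        summary.diagnostics.to_csv(out / "diagnostics.tsv", sep="\t", index=False)
    if manifest is not None:
        (out / "manifest.json").write_text(manifest.to_json())
    return out


def read_config(path) -> dict:
    """Flat key = value configuration file; '#' starts a comment."""
    cfg = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InputError(f"config {path}:{ln}: expected 'key = value'")
        key, val = (part.strip() for part in line.split("=", 1))
        for cast in (int, float):
            try:
                val = cast(val)
                break
            except ValueError:
                continue
        cfg[key] = val
    return cfg
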