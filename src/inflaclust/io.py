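"""File formats, run configuration, and reproducibility plumbing.

Expression matrices travel as plain TSV (genes in rows, header = samples) or
GCT 1.2. Duplicate gene symbols are collapsed to the row with the largest
median absolute deviation, the same keep-the-most-variable rule used for
probe-to-gene collapsing. All tables are written with sorted, deterministic
row/column order so reruns are byte-identical; every stochastic stage derives
its RNG stream from the single top-level seed by name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .scoring import ExpressionMatrix, ScoreMatrix, ScoreParams
from .signature_sets import SCORE_NAMES

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stream: str) -> int:
    """Deterministic named substream seed (< 2**31) from the top-level seed."""
    digest = hashlib.blake2b(f"{seed}:{stream}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, per duplicated symbol, the row with the largest MAD."""
    if not df.index.duplicated().any():
        return df
    mad = (df.sub(df.median(axis=1), axis=0)).abs().median(axis=1)
    order = np.argsort(-mad.to_numpy(), kind="stable")
    kept = df.iloc[order]
    kept = kept[~kept.index.duplicated(keep="first")]
    dropped = len(df) - len(kept)
    logger.info("collapsed %d duplicate gene rows by max MAD", dropped)
    return kept.loc[df.index.drop_duplicates()]


def read_expression(
    path: str | Path,
    fmt: str = "tsv",
    metadata: Optional[pd.DataFrame] = None,
) -> ExpressionMatrix:
    """Read a gene x sample log-expression matrix from TSV or GCT 1.2."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"expression file {path} is missing or empty")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version not in ("#1.2",):
                raise ValueError(f"{path}: unsupported GCT version line {version!r}")
            dims = fh.readline().split()
            n_rows, n_cols = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape != (n_rows, n_cols):
            raise ValueError(
                f"{path}: GCT header declares {n_rows}x{n_cols}, body is "
                f"{df.shape[0]}x{df.shape[1]}"
            )
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    df = _collapse_duplicates(df.astype(float))
    df.index.name = "gene"
    return ExpressionMatrix(df, metadata=metadata)


def write_expression(expr: ExpressionMatrix, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    df = expr.expr.sort_index()
    df = df[sorted(df.columns)]
    if fmt == "tsv":
        df.to_csv(path, sep="\t")
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t")
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: first column = sample id; optional columns
    tumor_type, time, event, true_cluster."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_score_matrix(scores: ScoreMatrix, path: str | Path, params: ScoreParams | None = None) -> None:
    """Score matrix TSV with a JSON sidecar recording params and scaling."""
    path = Path(path)
    scores.data.sort_index().to_csv(path, sep="\t")
    sidecar = {
        "columns": list(SCORE_NAMES),
        "scaling": scores.scaling,
        "scheme_fingerprint": scores.scheme_fingerprint,
        "params": asdict(params) if params is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_score_matrix(path: str | Path) -> ScoreMatrix:
    path = Path(path)
    data = pd.read_csv(path, sep="\t", index_col=0)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    scaling = None
    fingerprint = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        scaling = sidecar.get("scaling")
        fingerprint = sidecar.get("scheme_fingerprint")
    return ScoreMatrix(data=data[list(SCORE_NAMES)], scaling=scaling,
                       scheme_fingerprint=fingerprint)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class RunConfig:
    """Top-level pipeline configuration; one seed fans out to every stage."""

    expression: Optional[str] = None
    gene_sets_gmt: Optional[str] = None
    gene_sets_directions: Optional[str] = None
    metadata: Optional[str] = None
    out_dir: str = "inflaclust_out"
    alpha: float = 0.25
    standardize: bool = True
    k_range: tuple[int, ...] = tuple(range(2, 9))
    resamples: int = 500
    subsample_frac: float = 0.8
    min_silhouette: float = 0.25
    elbow_floor: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = RunConfig(**raw)
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        return cfg

    def echo(self, out_dir: str | Path) -> None:
        """Write the config verbatim into the output directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        (out / "run_config.yaml").write_text(yaml.safe_dump(d, sort_keys=True))

    def substream(self, name: str) -> int:
        return derive_seed(self.seed, name)
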