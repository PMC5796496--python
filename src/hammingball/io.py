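"""Delimited-text I/O, config parsing and run provenance.

Tab-separated text with a header row is the canonical tabular format
throughout; no binary formats are read or written.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

READ_COUNT_COLUMNS = ["variant_id", "sample_id", "variant_reads", "depth"]


def load_table(path, columns: list[str]) -> pd.DataFrame:
    """Read a TSV and check the expected header columns are present."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def load_read_counts(path):
    """Read a per-variant, per-sample read-count TSV.

    Expected columns: variant_id, sample_id, variant_reads, depth.
    Returns ``(r, d, variant_ids, sample_ids)`` with r, d of shape
    (n_variants, n_samples).  Rows violating 0 <= r <= d, d > 0 are
    rejected with the offending row named.
    """
    df = load_table(path, READ_COUNT_COLUMNS)
    bad = df[(df.variant_reads < 0) | (df.variant_reads > df.depth) | (df.depth <= 0)]
    if len(bad):
        row = bad.index[0]
        raise ValueError(
            f"{path}: row {row} violates 0 <= variant_reads <= depth "
            f"(variant_reads={bad.variant_reads.iloc[0]}, depth={bad.depth.iloc[0]})"
        )
    variants = list(dict.fromkeys(df.variant_id))
    samples = list(dict.fromkeys(df.sample_id))
    r = df.pivot(index="variant_id", columns="sample_id", values="variant_reads")
    d = df.pivot(index="variant_id", columns="sample_id", values="depth")
    if r.isna().any().any():
        raise ValueError(f"{path}: incomplete variant x sample grid")
    r = r.loc[variants, samples].to_numpy(dtype=np.int64)
    d = d.loc[variants, samples].to_numpy(dtype=np.int64)
    return r, d, variants, samples


def write_read_counts(path, r, d, variant_ids=None, sample_ids=None) -> None:
    """Write read counts in the canonical long TSV format."""
    r = np.atleast_2d(np.asarray(r).T).T
    d = np.atleast_2d(np.asarray(d).T).T
    n, s = r.shape
    variant_ids = variant_ids or [f"v{i+1}" for i in range(n)]
    sample_ids = sample_ids or [f"s{j+1}" for j in range(s)]
    rows = [
        (variant_ids[i], sample_ids[j], int(r[i, j]), int(d[i, j]))
        for i in range(n)
        for j in range(s)
    ]
    pd.DataFrame(rows, columns=READ_COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def load_design(path, genotype_coded: bool = False):
    """Read a design matrix TSV (rows = samples, header = covariate names).

    ``genotype_coded=True`` enforces the {0, 1, 2} SNP coding
    (0 = AA, 1 = AB, 2 = BB) and names the offending cell otherwise.
    """
    df = pd.read_csv(path, sep="\t")
    Z = df.to_numpy(dtype=float)
    if genotype_coded and not np.isin(Z, [0.0, 1.0, 2.0]).all():
        bad = np.argwhere(~np.isin(Z, [0.0, 1.0, 2.0]))[0]
        raise ValueError(
            f"{path}: covariate {df.columns[bad[1]]!r} row {bad[0]} is not in {{0,1,2}}"
        )
    return Z, list(df.columns)


def write_design(path, Z, names=None) -> None:
    Z = np.asarray(Z)
    names = names or [f"z{j+1}" for j in range(Z.shape[1])]
    pd.DataFrame(Z, columns=names).to_csv(path, sep="\t", index=False)


def load_response(path) -> np.ndarray:
    """Read a single-column response TSV (header row, one value per sample)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected a single response column, got {df.shape[1]}")
    return df.iloc[:, 0].to_numpy(dtype=float)


def write_response(path, y, name: str = "y") -> None:
    pd.DataFrame({name: np.asarray(y, dtype=float)}).to_csv(path, sep="\t", index=False)


def write_matrix(path, M) -> None:
    """Write a numeric matrix as TSV with generated column names."""
    M = np.atleast_2d(np.asarray(M))
    pd.DataFrame(M, columns=[f"c{j+1}" for j in range(M.shape[1])]).to_csv(
        path, sep="\t", index=False
    )


def load_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


@dataclass
class RunConfig:
    """Validated run settings; echoed verbatim into the output directory."""

    experiment: str
    out_dir: str
    seed: int = 0
    kernel: str = "block_hb"
    m: int = 1
    K: int = 10
    lam: float = 0.0
    iterations: int = 1000
    burn_in: int = 100
    thin: int = 1
    inputs: dict = field(default_factory=dict)
    hyper: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.iterations < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("iterations >= 1, burn_in >= 0, thin >= 1 required")
        if self.m < 0 or self.K < 1 or self.lam < 0:
            raise ValueError("need m >= 0, K >= 1, lam >= 0")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, input_paths: dict | None = None) -> Path:
    """Write a machine-readable manifest with seed, config and versions.

    Together with the input-file hashes this is enough provenance to
    re-run a directory bit-identically.
    """
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "versions": {
            "hammingball": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "input_hashes": {k: _sha256(v) for k, v in (input_paths or {}).items()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
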