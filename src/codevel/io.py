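"""On-disk formats: TSV count tables (primary), BIOM (JSON), metadata TSV.

TSV dialect: UTF-8, tab-separated, samples as rows with the sample id in
the first column, optional '#'-prefixed header comment lines carrying
provenance (seed, config hash).  BIOM tables are read/written in the JSON
serialization and round-trip identically with the TSV carrier.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

try:
    import biom
    from biom.table import Table as _BiomTable
    HAVE_BIOM = True
except ImportError:  # pragma: no cover - biom ships with the environment
    HAVE_BIOM = False


def _detect_format(path: str | Path) -> str:
    return "biom" if str(path).endswith(".biom") else "tsv"


def read_counts(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read an integer count matrix (samples x features).

    Negative or non-numeric entries raise with the offending coordinates;
    ragged TSV rows raise naming the line number.
    """
    fmt = format or _detect_format(path)
    if fmt == "biom":
        if not HAVE_BIOM:
            raise RuntimeError("biom-format is not installed")
        table = biom.load_table(str(path))
        df = table.to_dataframe(dense=True).T  # observations x samples -> s x f
        mat = df.to_numpy()
    elif fmt == "tsv":
        lines = [ln for ln in Path(path).read_text().splitlines()
                 if ln and not ln.startswith("#")]
        widths = {len(ln.split("\t")) for ln in lines}
        if len(widths) > 1:
            for i, ln in enumerate(lines[1:], start=2):
                if len(ln.split("\t")) != len(lines[0].split("\t")):
                    raise ValueError(f"ragged TSV: line {i} has "
                                     f"{len(ln.split(chr(9)))} fields")
        df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t",
                         index_col=0)
        mat = df.to_numpy()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids")
    if not np.issubdtype(np.asarray(mat).dtype, np.number):
        bad = np.argwhere(~np.vectorize(np.isreal)(mat))
        r, c = bad[0]
        raise ValueError(f"non-numeric entry at row {df.index[r]!r}, "
                         f"column {df.columns[c]!r}")
    if np.isnan(mat.astype(float)).any():
        r, c = np.argwhere(np.isnan(mat.astype(float)))[0]
        raise ValueError(f"non-numeric entry at row {df.index[r]!r}, "
                         f"column {df.columns[c]!r}")
    if (mat < 0).any():
        r, c = np.argwhere(mat < 0)[0]
        raise ValueError(f"negative count at row {df.index[r]!r}, "
                         f"column {df.columns[c]!r}")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path: str | Path,
                 format: str | None = None, *,
                 comments: list[str] | None = None) -> None:
    """Write a count matrix as TSV (default) or JSON-serialized BIOM."""
    fmt = format or _detect_format(path)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        write_tsv(counts, path, comments=comments)
    elif fmt == "biom":
        if not HAVE_BIOM:
            raise RuntimeError("biom-format is not installed")
        table = _BiomTable(counts.to_numpy().T,
                           observation_ids=[str(c) for c in counts.columns],
                           sample_ids=[str(i) for i in counts.index])
        path.write_text(table.to_json(generated_by="codevel"))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_tsv(frame: pd.DataFrame, path: str | Path, *,
              comments: list[str] | None = None,
              index: bool = True, float_format: str | None = None) -> None:
    """Write a TSV with optional '#'-prefixed provenance header lines.

    Model-output tables are written with a fixed reporting precision
    (``float_format='%.6g'``) so reruns hash identically down to the last
    digit regardless of sub-nanoscale optimizer jitter."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format=float_format)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (skips '#' comments)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, **kwargs)
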