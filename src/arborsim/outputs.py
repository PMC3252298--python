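"""Output writers: plain tab-separated time series, optional HDF5 mirror.

Column 1 is time in seconds; one column per recorded variable; ``#``-prefixed
header lines carry the variable paths and run provenance so external tools can
ingest the file directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_tsv", "write_hdf5", "read_tsv"]


def write_tsv(path, times, columns: dict[str, np.ndarray],
              header: dict[str, str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = list(columns)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# columns: time/s\t" + "\t".join(f"{lab}/V" for lab in labels) + "\n")
        data = np.column_stack([np.asarray(times)] + [np.asarray(columns[lab]) for lab in labels])
        for row in data:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_tsv(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read back a file written by :func:`write_tsv`."""
    labels: list[str] = []
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# columns:"):
                cols = line.split(":", 1)[1].strip().split("\t")
                labels = [c.rsplit("/", 1)[0] for c in cols[1:]]
            elif line.startswith("#") or not line:
                continue
            else:
                rows.append([float(x) for x in line.split("\t")])
    data = np.asarray(rows)
    times = data[:, 0] if rows else np.zeros(0)
    return times, {lab: data[:, i + 1] for i, lab in enumerate(labels)}


def write_hdf5(path, times, columns: dict[str, np.ndarray],
               attrs: dict[str, str] | None = None) -> None:
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("time", data=np.asarray(times))
        grp = h5.create_group("variables")
        for lab, vals in columns.items():
            grp.create_dataset(lab, data=np.asarray(vals))
        for key, val in (attrs or {}).items():
            h5.attrs[key] = val
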