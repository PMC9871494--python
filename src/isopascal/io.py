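"""Readers and writers for the tabular formats the pipeline exchanges.

Raw GC-MS input is a delimited table with a column ``Name`` (fragment key,
matching the registry naming convention exactly) and a column ``Area``, one
row per nominal mass in ascending order per fragment; an optional ``Sample``
column groups clusters, and an optional ``Mz`` column allows out-of-order
rows to be re-sorted (with a warning).  Delimiters are restricted to tab,
comma and semicolon; decimal separator is ".".

All output tables start with a schema-version comment line (``# isopascal
<kind> v1``) and are read back with ``comment="#"``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from isopascal.chem_fragments import Registry
from isopascal.correction import CID, RawIsotopicCluster
from isopascal.fractional_contribution import LabelingSample

__all__ = [
    "read_raw_table", "write_raw_table",
    "write_cid_table", "read_cid_table", "cid_table", "samples_from_cid_table",
    "write_table",
]

_DELIMITERS = ("\t", ",", ";")


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                counts = {d: line.count(d) for d in _DELIMITERS}
                best = max(counts, key=counts.get)
                if counts[best] == 0:
                    raise ValueError(
                        f"{path}: could not detect a tab/comma/semicolon "
                        "delimiter in the header"
                    )
                return best
    raise ValueError(f"{path}: file is empty")


def read_raw_table(
    path: str | Path,
    registry: Registry,
) -> list[RawIsotopicCluster]:
    """Read raw isotopic clusters grouped by sample and fragment.

    Fragment names are validated against *registry*; an unknown name is an
    error listing the valid names.  Rows are taken in file order as ascending
    mass shifts unless an ``Mz`` column is present, in which case out-of-order
    clusters are re-sorted with a warning.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    for col in ("Name", "Area"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    unknown = sorted(set(df["Name"]) - set(registry.names))
    if unknown:
        raise ValueError(
            f"{path}: unknown fragment name(s) {unknown}; valid names: "
            f"{', '.join(registry.names)}"
        )
    if not np.issubdtype(df["Area"].dtype, np.number):
        raise ValueError(f"{path}: non-numeric values in 'Area'")
    if "Sample" not in df.columns:
        df["Sample"] = ""
    clusters = []
    for (sample, name), grp in df.groupby(["Sample", "Name"], sort=False):
        if "Mz" in grp.columns:
            mz = grp["Mz"].to_numpy()
            if np.any(np.diff(mz) < 0):
                warnings.warn(
                    f"{path}: out-of-order masses for {name} in sample "
                    f"{sample!r}; re-sorting", stacklevel=2)
                grp = grp.sort_values("Mz")
        clusters.append(RawIsotopicCluster(
            fragment=name, areas=grp["Area"].to_numpy(float), sample=sample))
    return clusters


def write_raw_table(clusters: list[RawIsotopicCluster], path: str | Path) -> None:
    """Write clusters as a Name/Area table (with Sample and shift columns)."""
    rows = []
    for c in clusters:
        for k, a in enumerate(c.areas):
            rows.append({"Sample": c.sample, "Name": c.fragment,
                         "Shift": k, "Area": a})
    _write(pd.DataFrame(rows), path, "raw-table")


def cid_table(cids: list[CID]) -> pd.DataFrame:
    """Long-format table of corrected CIDs: one row per sample × fragment ×
    isotopologue, with per-fragment mean_enrichment and residual columns."""
    rows = []
    for c in cids:
        for i, f in enumerate(c.fractions):
            rows.append({
                "sample": c.sample,
                "fragment": c.fragment,
                "isotopologue": i,
                "isotopologue_fraction": f,
                "mean_enrichment": c.mean_enrichment,
                "residual": c.residual,
                "warnings": "; ".join(c.warnings),
            })
    return pd.DataFrame(rows)


def write_cid_table(cids: list[CID], path: str | Path) -> None:
    _write(cid_table(cids), path, "cid-table")


def read_cid_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format CID table (corrected output, or external data with
    at least sample/fragment/isotopologue/isotopologue_fraction columns)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    required = {"fragment", "isotopologue", "isotopologue_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def samples_from_cid_table(df: pd.DataFrame) -> list[LabelingSample]:
    """Group a long CID table carrying condition/time_h/replicate metadata
    into :class:`LabelingSample` objects for the FC stage."""
    for col in ("condition", "time_h", "replicate"):
        if col not in df.columns:
            raise ValueError(f"CID table lacks metadata column {col!r}")
    samples = []
    for (cond, t, rep), grp in df.groupby(
            ["condition", "time_h", "replicate"], sort=True):
        cids = {}
        for frag, g in grp.groupby("fragment", sort=False):
            g = g.sort_values("isotopologue")
            idx = g["isotopologue"].to_numpy()
            if not np.array_equal(idx, np.arange(idx.size)):
                raise ValueError(
                    f"fragment {frag}: isotopologue indices not contiguous "
                    f"for ({cond}, t={t}, rep={rep})"
                )
            cids[frag] = g["isotopologue_fraction"].to_numpy(float)
        samples.append(LabelingSample(
            condition=str(cond), time_h=float(t), replicate=rep, cids=cids))
    return samples


def samples_to_cid_table(samples: list[LabelingSample]) -> pd.DataFrame:
    """Inverse of :func:`samples_from_cid_table`."""
    rows = []
    for s in samples:
        for frag in s.cids:
            for i, f in enumerate(s.fractions(frag)):
                rows.append({
                    "sample": f"{s.condition}_T{s.time_h:g}_rep{s.replicate}",
                    "condition": s.condition,
                    "time_h": s.time_h,
                    "replicate": s.replicate,
                    "fragment": frag,
                    "isotopologue": i,
                    "isotopologue_fraction": f,
                })
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write any result table with the schema-version header."""
    _write(df, path, kind)


def _write(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    with open(path, "w") as fh:
        fh.write(f"# isopascal {kind} v1\n")
        df.to_csv(fh, sep=sep, index=False)
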