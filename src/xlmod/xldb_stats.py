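"""Statistics over a curated cross-link table (XLdb-style).

Reads a spreadsheet or CSV of literature-curated DSS/BS3 cross-links -
publication, PDB entry, the two linked residues and, when available, their
Euclidean and SAS distances - and derives the distance statistics that
calibrate virtual cross-link sampling: histograms, the empirical cumulative
distribution, and the per-bin probabilities conditioned on the 34 A ruler.

The reader is schema-tolerant: columns are located by normalised header
names, so "SAS distance [A]", "SASD" or "dSAS" all work.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structure_model import AtomSpec
from .virtual_xl import BinDistribution, XLDB_BINS

__all__ = [
    "XldbRecord",
    "read_xldb",
    "count_by_type",
    "count_publications",
    "Ecdf",
    "ecdf",
    "bin_probabilities",
    "fraction_within",
    "histogram_table",
    "ecdf_table",
]

_COLUMN_SYNONYMS = {
    "publication": {"publication", "source", "reference", "pub", "paper", "pubid"},
    "pdb_id": {"pdb", "pdbid", "pdb_id", "pdbentry"},
    "residue1": {"residue1", "atom1", "site1", "spec1", "link1", "res1"},
    "residue2": {"residue2", "atom2", "site2", "spec2", "link2", "res2"},
    "type": {"type", "linktype", "xltype", "category"},
    "euclidean": {"euclidean", "euclideandistance", "euc", "ed", "dxyz"},
    "sasd": {"sasd", "sasdistance", "sas", "dsas", "sasdist"},
}
_MANDATORY = ("publication", "pdb_id", "residue1")


@dataclass
class XldbRecord:
    publication: str
    pdb_id: str
    spec1: AtomSpec
    spec2: AtomSpec | None
    link_type: str  # intra | inter | mono
    euclidean: float | None = None
    sasd: float | None = None


def _normalize(name: str) -> str:
    return "".join(ch for ch in str(name).lower() if ch.isalnum())


def _locate_columns(columns: Sequence[str]) -> dict[str, str]:
    found: dict[str, str] = {}
    for col in columns:
        norm = _normalize(col)
        for key, synonyms in _COLUMN_SYNONYMS.items():
            if key not in found and norm in synonyms:
                found[key] = col
    return found


def _parse_spec(value) -> AtomSpec | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() in ("nan", "none", "-"):
        return None
    return AtomSpec.from_string(text)


def read_xldb(source, dedupe: bool = False) -> list[XldbRecord]:
    """Read a cross-link table from .csv/.tsv/.xlsx (or a DataFrame).

    The header row identifies columns by name; publication, PDB entry and
    the first linked residue are mandatory.  Link type is taken from a type
    column when present, else inferred (no second residue: mono; different
    chains: inter; same chain: intra).  Duplicated rows are kept with a
    warning by default, or dropped with ``dedupe=True``.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        path = Path(source)
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path)
        elif path.suffix.lower() == ".tsv":
            df = pd.read_csv(path, sep="\t")
        else:
            df = pd.read_csv(path)
    cols = _locate_columns(df.columns)
    missing = [k for k in _MANDATORY if k not in cols]
    if missing:
        raise ValueError(f"cross-link table is missing mandatory columns: {missing}")

    if df.duplicated().any():
        n_dup = int(df.duplicated().sum())
        if dedupe:
            df = df.drop_duplicates()
            warnings.warn(f"dropped {n_dup} duplicated cross-link rows", stacklevel=2)
        else:
            warnings.warn(f"table contains {n_dup} duplicated rows (kept)", stacklevel=2)

    records = []
    for _, row in df.iterrows():
        spec1 = _parse_spec(row[cols["residue1"]])
        if spec1 is None:
            raise ValueError(f"row {_}: first residue is empty")
        spec2 = _parse_spec(row[cols["residue2"]]) if "residue2" in cols else None
        if "type" in cols and isinstance(row[cols["type"]], str) and row[cols["type"]].strip():
            link_type = row[cols["type"]].strip().lower()
        elif spec2 is None:
            link_type = "mono"
        else:
            link_type = "inter" if spec1.chain_id != spec2.chain_id else "intra"

        def _num(key):
            if key not in cols:
                return None
            v = row[cols[key]]
            try:
                f = float(v)
            except (TypeError, ValueError):
                return None
            return f if np.isfinite(f) else None

        records.append(XldbRecord(
            publication=str(row[cols["publication"]]),
            pdb_id=str(row[cols["pdb_id"]]),
            spec1=spec1,
            spec2=spec2,
            link_type=link_type,
            euclidean=_num("euclidean"),
            sasd=_num("sasd"),
        ))
    return records


def count_by_type(records: Iterable[XldbRecord]) -> Counter:
    return Counter(r.link_type for r in records)


def count_publications(records: Iterable[XldbRecord]) -> int:
    return len({r.publication for r in records})


class Ecdf:
    """Right-continuous empirical cumulative distribution function."""

    def __init__(self, values: Sequence[float]):
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise ValueError("ECDF needs at least one finite value")
        self._sorted = np.sort(arr)
        self.n = arr.size

    def __call__(self, x) -> np.ndarray | float:
        q = np.searchsorted(self._sorted, np.asarray(x, dtype=float), side="right")
        out = q / self.n
        return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def ecdf(values: Sequence[float]) -> Ecdf:
    """ECDF of the given distances; F(max) = 1, F(x < min) = 0."""
    return Ecdf(values)


def fraction_within(distances: Sequence[float], cutoff: float = 34.0) -> float:
    """Fraction of finite distances not exceeding the cutoff."""
    arr = np.asarray(distances, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite distances")
    return float((arr <= cutoff).mean())


def histogram_table(distances: Sequence[float], bin_width: float = 2.0,
                    max_dist: float | None = None) -> str:
    """Distance histogram as 'lo<TAB>hi<TAB>count' lines."""
    arr = np.asarray(distances, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite distances")
    hi = float(max_dist) if max_dist is not None else float(np.ceil(arr.max()))
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    lines = ["lo\thi\tcount"]
    for lo, up, c in zip(edges[:-1], edges[1:], counts):
        lines.append(f"{lo:.1f}\t{up:.1f}\t{int(c)}")
    return "\n".join(lines) + "\n"


def ecdf_table(distances: Sequence[float], step: float = 1.0,
               max_dist: float | None = None) -> str:
    """The empirical CDF evaluated on a regular grid, as delimited text."""
    f = ecdf(distances)
    hi = float(max_dist) if max_dist is not None else float(f._sorted[-1])
    xs = np.arange(0.0, hi + step / 2, step)
    lines = ["distance\tcumulative_fraction"]
    for x in xs:
        lines.append(f"{x:.1f}\t{float(f(x)):.6f}")
    return "\n".join(lines) + "\n"


def bin_probabilities(
    distances: Sequence[float],
    edges: Sequence[float] = XLDB_BINS.edges,
) -> BinDistribution:
    """Empirical bin probabilities conditioned on the distance ruler.

    Counts distances into the given bins (half-open, last bin closed) and
    normalises by the number of distances inside [first, last] edge - i.e.
    the distribution of cross-links eligible as virtual links.
    """
    arr = np.asarray(distances, dtype=float)
    arr = arr[np.isfinite(arr)]
    counts, _ = np.histogram(arr, bins=np.asarray(edges, dtype=float))
    total = counts.sum()
    if total == 0:
        raise ValueError("no distances within the bin range")
    return BinDistribution(edges=tuple(float(e) for e in edges),
                           probabilities=tuple((counts / total).tolist()))
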