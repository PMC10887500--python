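"""Long-format Y-STR genotype tables.

Input is a CSV/TSV with columns pedigree, sample, marker, allele(s).  Alleles
are capillary-electrophoresis repeat counts, possibly microvariants (23.2);
multi-copy loci and duplications carry several values per cell, separated by
a configurable delimiter.  Every sample must be typed for the same marker
set; incomplete profiles are a hard error unless explicitly dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeTable",
    "IncompleteProfileError",
    "parse_alleles",
    "format_alleles",
    "load_haplotypes",
    "write_haplotypes",
    "drop_incomplete",
]

COLUMNS = ["pedigree_id", "sample_id", "marker", "alleles"]

_COLUMN_ALIASES = {
    "pedigree": "pedigree_id",
    "pedigree_id": "pedigree_id",
    "ped": "pedigree_id",
    "sample": "sample_id",
    "sample_id": "sample_id",
    "id": "sample_id",
    "marker": "marker",
    "locus": "marker",
    "y-str": "marker",
    "ystr": "marker",
    "allele": "alleles",
    "alleles": "alleles",
    "allele(s)": "alleles",
}


class IncompleteProfileError(ValueError):
    """A sample lacks data for one or more markers of the shared marker set."""

    def __init__(self, missing: list[tuple[str, str, str]]):
        self.missing = missing  # (pedigree_id, sample_id, marker)
        ped, sample, marker = missing[0]
        detail = f"sample {sample!r} (pedigree {ped!r}) lacks marker {marker!r}"
        if len(missing) > 1:
            detail += f" (+{len(missing) - 1} further missing cells)"
        super().__init__(
            detail + "; either that Y-STR or that individual must be removed "
            "before analysis"
        )


def parse_alleles(cell: str | float | int, delimiter: str = ",") -> tuple[float, ...]:
    """Parse one allele cell into a sorted tuple of repeat counts.

    Accepts a single number or several joined by ``delimiter`` (e.g.
    ``"22,23.2,25"``).  Repeat counts must be positive numbers; microvariant
    nomenclature (one decimal place) is preserved exactly.
    """
    if isinstance(cell, (int, float)):
        parts = [str(cell)]
    else:
        parts = [p.strip() for p in str(cell).split(delimiter)]
    alleles = []
    for part in parts:
        if not part:
            raise ValueError("empty allele value (null alleles are not supported)")
        try:
            value = float(part)
        except ValueError:
            raise ValueError(f"non-numeric allele value {part!r}") from None
        if value <= 0:
            raise ValueError(f"allele value must be positive, got {part!r}")
        alleles.append(round(value, 1))
    return tuple(sorted(alleles))


def format_alleles(alleles: tuple[float, ...], delimiter: str = ",") -> str:
    """Inverse of :func:`parse_alleles`: tenth-precision decimal strings."""
    return delimiter.join(
        str(int(a)) if float(a).is_integer() else f"{a:.1f}" for a in alleles
    )


@dataclass
class HaplotypeTable:
    """Per (pedigree, sample, marker) multisets of allele repeat counts.

    ``data`` is a tidy DataFrame with columns pedigree_id, sample_id, marker
    and alleles (a sorted tuple of floats).  ``markers`` fixes the marker
    order shared by all downstream feature vectors.
    """

    data: pd.DataFrame
    markers: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.markers:
            self.markers = sorted(self.data["marker"].unique())

    @property
    def samples(self) -> list[tuple[str, str]]:
        """(pedigree_id, sample_id) pairs in first-seen order."""
        seen = self.data[["pedigree_id", "sample_id"]].drop_duplicates()
        return list(seen.itertuples(index=False, name=None))

    def alleles(self, pedigree_id: str, sample_id: str, marker: str) -> tuple[float, ...]:
        rows = self.data[
            (self.data["pedigree_id"] == pedigree_id)
            & (self.data["sample_id"] == sample_id)
            & (self.data["marker"] == marker)
        ]
        if rows.empty:
            raise KeyError((pedigree_id, sample_id, marker))
        return rows["alleles"].iloc[0]

    def genotypes(self, pedigree_id: str, marker: str) -> dict[str, tuple[float, ...]]:
        """sample_id -> allele multiset for one pedigree at one marker."""
        rows = self.data[
            (self.data["pedigree_id"] == pedigree_id) & (self.data["marker"] == marker)
        ]
        return dict(zip(rows["sample_id"], rows["alleles"]))

    def pedigree_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["pedigree_id"]))

    def missing_cells(self) -> list[tuple[str, str, str]]:
        """(pedigree, sample, marker) cells absent from the table."""
        have = set(
            self.data[["pedigree_id", "sample_id", "marker"]].itertuples(
                index=False, name=None
            )
        )
        return [
            (ped, sample, marker)
            for ped, sample in self.samples
            for marker in self.markers
            if (ped, sample, marker) not in have
        ]

    def validate_complete(self) -> None:
        missing = self.missing_cells()
        if missing:
            raise IncompleteProfileError(missing)


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _COLUMN_ALIASES:
            renames[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=renames)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"haplotype table is missing column(s) {missing}; expected "
            "pedigree, sample, marker, allele(s)"
        )
    return df[COLUMNS]


def load_haplotypes(
    path: str | Path,
    allele_delimiter: str = ",",
    require_complete: bool = True,
) -> HaplotypeTable:
    """Load a long-format genotype CSV/TSV into a :class:`HaplotypeTable`.

    Both one-row-per-(sample, marker) with delimiter-joined alleles and
    one-row-per-allele layouts are accepted; both normalize to multisets.
    The marker set is the union over all rows.  With ``require_complete``
    (default) an incomplete profile raises :class:`IncompleteProfileError`
    naming the sample and marker.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, comment="#", skipinitialspace=True)
    raw = _normalize_columns(raw)
    raw["pedigree_id"] = raw["pedigree_id"].astype(str).str.strip()
    raw["sample_id"] = raw["sample_id"].astype(str).str.strip()
    raw["marker"] = raw["marker"].astype(str).str.strip()

    records = []
    for (ped, sample, marker), group in raw.groupby(
        ["pedigree_id", "sample_id", "marker"], sort=False
    ):
        alleles: list[float] = []
        for cell in group["alleles"]:
            if pd.isna(cell):
                raise ValueError(
                    f"empty allele cell for sample {sample!r}, marker {marker!r}"
                )
            alleles.extend(parse_alleles(cell, allele_delimiter))
        records.append((ped, sample, marker, tuple(sorted(alleles))))
    table = HaplotypeTable(pd.DataFrame(records, columns=COLUMNS))
    if require_complete:
        table.validate_complete()
    return table


def write_haplotypes(
    table: HaplotypeTable, path: str | Path, allele_delimiter: str = ","
) -> None:
    """Write the table back to CSV/TSV (one row per sample-marker cell)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    out = table.data.copy()
    out["alleles"] = out["alleles"].map(
        lambda a: format_alleles(a, allele_delimiter)
    )
    out.to_csv(path, sep=sep, index=False)


def drop_incomplete(
    table: HaplotypeTable, mode: Literal["samples", "markers"] = "samples"
) -> HaplotypeTable:
    """Remove offending samples (or markers) until every cell is populated.

    mode="samples" drops each sample with any missing marker; mode="markers"
    drops each marker missing from any sample.  Removals are logged.
    """
    missing = table.missing_cells()
    if not missing:
        return table
    data = table.data
    if mode == "samples":
        bad = {(ped, sample) for ped, sample, _ in missing}
        for ped, sample in sorted(bad):
            logger.warning(
                "dropping sample %s (pedigree %s): incomplete profile", sample, ped
            )
        keep = ~data[["pedigree_id", "sample_id"]].apply(tuple, axis=1).isin(bad)
        result = HaplotypeTable(data[keep].reset_index(drop=True), list(table.markers))
    elif mode == "markers":
        bad_markers = {marker for _, _, marker in missing}
        for marker in sorted(bad_markers):
            logger.warning("dropping marker %s: missing in >=1 sample", marker)
        keep = ~data["marker"].isin(bad_markers)
        result = HaplotypeTable(
            data[keep].reset_index(drop=True),
            [m for m in table.markers if m not in bad_markers],
        )
    else:
        raise ValueError(f"mode must be 'samples' or 'markers', got {mode!r}")
    result.validate_complete()
    return result
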