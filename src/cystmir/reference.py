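"""Reference containers: the miRNA catalogue, spike-in manifest and barcode map.

The miRNA reference holds one row per *merged mature* entry.  Identical mature
sequences encoded at several genomic loci (multicopy miRNAs) are a single row
whose name carries the member count in parentheses, e.g. ``miR-24-1(2)``.
Each mature belongs to exactly one cistron cluster (miRNAs co-transcribed from
one primary transcript, ``cluster-<name>(N)``) and one sequence family
(``seqfam-<name>(N)``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

_VALID_NT = re.compile(r"^[ACGT]+$")
_PAREN = re.compile(r"\((\d+)\)$")

REFERENCE_COLUMNS = ["name", "sequence", "copy_group", "n_copies", "cluster", "family"]


def _member_count(unit_name: str) -> int | None:
    m = _PAREN.search(unit_name)
    return int(m.group(1)) if m else None


@dataclass
class MiRNAReference:
    """Catalogue of merged mature miRNAs with grouping annotations.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``name, sequence, copy_group, n_copies, cluster, family``;
        one row per merged mature entry (unique name and unique sequence).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REFERENCE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"reference table missing columns: {missing}")
        t = self.table
        if t["name"].duplicated().any():
            dup = t.loc[t["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate mature name in reference: {dup}")
        if t["sequence"].duplicated().any():
            dup = t.loc[t["sequence"].duplicated(), "sequence"].iloc[0]
            raise ValueError(
                "duplicate mature sequence mapped to different entries: " + dup
            )
        for seq in t["sequence"]:
            if not _VALID_NT.match(seq):
                raise ValueError(f"invalid mature sequence: {seq!r}")
            if not 19 <= len(seq) <= 25:
                raise ValueError(f"mature length outside 19-25 nt: {seq!r}")
        for col in ("cluster", "family"):
            sizes = t.groupby(col).size()
            for unit, n in sizes.items():
                declared = _member_count(str(unit))
                if declared is not None and declared != n:
                    raise ValueError(
                        f"{col} {unit!r} declares {declared} members, found {n}"
                    )

    # -- accessors -------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    @property
    def seq_to_name(self) -> dict[str, str]:
        return dict(zip(self.table["sequence"], self.table["name"]))

    def membership(self, system: str) -> pd.Series:
        """Map merged mature name -> aggregation unit for a unit system."""
        if system == "mature-merged":
            return pd.Series(self.table["name"].values, index=self.table["name"])
        if system in ("cistron", "family"):
            col = "cluster" if system == "cistron" else "family"
            return pd.Series(self.table[col].values, index=self.table["name"])
        raise ValueError(f"unknown unit system: {system!r}")

    # -- IO --------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.table[REFERENCE_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MiRNAReference":
        return cls(pd.read_csv(path, sep="\t", dtype={"n_copies": int}))


@dataclass
class CalibratorManifest:
    """Synthetic calibrator oligoribonucleotides spiked at known molar amounts.

    Columns: ``name, sequence, fmol`` (amount added per library).  Calibrator
    read counts anchor the conversion of miRNA read counts to femtomoles.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("name", "sequence", "fmol"):
            if col not in self.table.columns:
                raise ValueError(f"calibrator manifest missing column {col!r}")
        if (self.table["fmol"] <= 0).any():
            raise ValueError("calibrator amounts must be positive")
        if self.table["sequence"].duplicated().any():
            raise ValueError("duplicate calibrator sequences")

    @property
    def total_fmol(self) -> float:
        return float(self.table["fmol"].sum())

    @property
    def seq_to_name(self) -> dict[str, str]:
        return dict(zip(self.table["sequence"], self.table["name"]))

    def to_tsv(self, path) -> None:
        self.table[["name", "sequence", "fmol"]].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CalibratorManifest":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class BarcodeMap:
    """Sample -> 5' barcode assignment used for demultiplexing.

    All barcodes must share one length, be pairwise distinct and contain only
    uppercase ACGT.  Reads are assigned by exact prefix match.
    """

    barcodes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("empty barcode map")
        lengths = {len(b) for b in self.barcodes.values()}
        if len(lengths) != 1:
            raise ValueError("barcodes must all have the same length")
        if len(set(self.barcodes.values())) != len(self.barcodes):
            raise ValueError("barcode collision between samples")
        for b in self.barcodes.values():
            if not _VALID_NT.match(b):
                raise ValueError(f"invalid barcode {b!r}")

    @property
    def length(self) -> int:
        return len(next(iter(self.barcodes.values())))

    def items(self):
        return self.barcodes.items()

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": list(self.barcodes), "barcode": list(self.barcodes.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BarcodeMap":
        t = pd.read_csv(path, sep="\t")
        return cls(dict(zip(t["sample"], t["barcode"])))
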