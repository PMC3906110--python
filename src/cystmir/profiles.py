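"""Count matrices, unit-system aggregation, CPM normalization and absolute quantification.

Mature miRNA counts can be viewed in three unit systems: ``mature-merged``
(identical multicopy sequences merged), ``cistron`` (co-transcribed precursor
clusters summed) and ``family`` (extensive-sequence-similarity families
summed).  Aggregation conserves reads, so per-sample totals are identical in
all three systems.  Differential-abundance analyses of cellular specimens use
the cistron system (cluster members are co-transcribed and correlated), while
extracellular/biofluid specimens use the mature-merged system, since secretion
and stability in the biofluid decouple cluster members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cystmir.reference import CalibratorManifest, MiRNAReference

UNIT_SYSTEMS = ("mature-merged", "cistron", "family")


@dataclass
class CountMatrix:
    """Integer read counts, miRNA unit x sample.

    Attributes
    ----------
    counts : pandas.DataFrame
        Nonnegative integers, index = unit names, columns = sample ids.
    unit_system : str
        One of ``mature-merged``, ``cistron``, ``family``.
    """

    counts: pd.DataFrame
    unit_system: str = "mature-merged"

    def __post_init__(self) -> None:
        if self.unit_system not in UNIT_SYSTEMS:
            raise ValueError(f"unknown unit system {self.unit_system!r}")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = self.counts.astype(np.int64)

    @property
    def totals(self) -> pd.Series:
        """Per-sample total miRNA reads (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("unit").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, unit_system: str = "mature-merged") -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), unit_system)


def aggregate(mature: CountMatrix, ref: MiRNAReference, system: str) -> CountMatrix:
    """Sum merged-mature counts into the requested unit system.

    Parameters
    ----------
    mature : CountMatrix
        Counts in the ``mature-merged`` system (the substrate for all
        aggregation, preventing double-counting of multicopy sequences).
    ref : MiRNAReference
    system : str
        Target unit system.

    Returns
    -------
    CountMatrix
        Unit names follow the ``(N)`` member-count convention of the
        reference (``cluster-...(N)`` / ``seqfam-...(N)``).
    """
    if system not in UNIT_SYSTEMS:
        raise ValueError(f"unknown unit system {system!r}")
    if mature.unit_system != "mature-merged":
        raise ValueError("aggregate() expects mature-merged input counts")
    unknown = set(mature.counts.index) - set(ref.names)
    if unknown:
        raise ValueError(f"matures absent from reference: {sorted(unknown)[:5]}")
    if system == "mature-merged":
        return CountMatrix(mature.counts.copy(), system)
    mapping = ref.membership(system)
    grouped = mature.counts.groupby(mapping.reindex(mature.counts.index)).sum()
    grouped.index.name = None
    return CountMatrix(grouped, system)


def to_cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million miRNA counts: ``CPM_gi = 1e6 * y_gi / total_i``.

    Columns of the result sum to 1e6 (up to float rounding).  A sample with a
    zero total cannot be normalized and raises an error naming it.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = mat.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero miRNA total for sample(s): {list(zero.index)}")
    return mat.div(totals, axis=1) * 1e6


def quantify_absolute(
    mirna_totals: pd.Series,
    calibrator_reads: pd.Series,
    manifest: CalibratorManifest,
    input_ug: pd.Series | float,
    rna_ng_per_ml: pd.Series | float | None = None,
) -> pd.DataFrame:
    """Spike-in anchored absolute quantification of miRNA content.

    Calibrator oligoribonucleotides added at known femtomole amounts convert
    read counts to moles linearly::

        miRNA_fmol   = miRNA_reads * (total calibrator fmol / calibrator reads)
        fmol_per_ug  = miRNA_fmol / input RNA (ug)
        fmol_per_l   = fmol_per_ug * RNA yield (ng RNA per ml urine)

    (ng/ml is numerically ug/l, so the product is fmol per liter of urine.)

    Samples with zero calibrator reads are flagged unquantifiable (NaN), never
    reported as zero content.
    """
    samples = mirna_totals.index
    cal = calibrator_reads.reindex(samples).fillna(0)
    ug = pd.Series(input_ug, index=samples) if np.isscalar(input_ug) else input_ug.reindex(samples)
    out = pd.DataFrame(index=samples)
    quantifiable = cal > 0
    if (~quantifiable).any():
        warnings.warn(
            f"{(~quantifiable).sum()} sample(s) with zero calibrator reads are "
            "unquantifiable",
            stacklevel=2,
        )
    fmol = np.where(quantifiable, mirna_totals * manifest.total_fmol / cal.where(quantifiable), np.nan)
    out["mirna_fmol"] = fmol
    out["fmol_per_ug"] = out["mirna_fmol"] / ug
    if rna_ng_per_ml is not None:
        conc = (
            pd.Series(rna_ng_per_ml, index=samples)
            if np.isscalar(rna_ng_per_ml)
            else rna_ng_per_ml.reindex(samples)
        )
        out["fmol_per_l"] = out["fmol_per_ug"] * conc
    out["quantifiable"] = quantifiable.values
    return out
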