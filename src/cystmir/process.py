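"""Library processing: demultiplexing, adapter trimming and read annotation.

Reads from a multiplexed small-RNA cDNA library carry a sample barcode at the
5' end and run into the 3' sequencing adapter.  Processing proceeds in three
stages: reads are split into samples by exact barcode-prefix match, the 3'
adapter suffix is removed, and the resulting inserts are annotated against
the calibrator manifest, the miRNA catalogue (exact match, then a bounded
edit tolerance that records isomiR-style variants) and a genome sequence for
the residual unannotated class.

Annotation priority: calibrator (exact) > mature miRNA (exact, <=1 internal
substitution, end trims within 2 nt, or <=3 untemplated 3' additions) >
genome-matching unannotated > discarded.  Reads matching a multicopy mature
sequence are counted once under the merged "(N)" entry, which is how the
catalogue stores them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from cystmir.profiles import CountMatrix
from cystmir.reference import BarcodeMap, CalibratorManifest, MiRNAReference

MIN_INSERT = 16
MAX_INSERT = 30
MIN_ADAPTER_OVERLAP = 6

CATEGORIES = ("calibrator", "mature", "unannotated-genomic", "discarded")


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def read_fastq_sequences(path) -> list[str]:
    """Sequences of a FASTQ file (plain or gzip) as uppercase strings."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]


def demultiplex(reads, barcodes: BarcodeMap):
    """Split reads into samples by exact barcode-prefix match.

    Parameters
    ----------
    reads : iterable of str
        Raw read sequences (barcode still attached).
    barcodes : BarcodeMap

    Returns
    -------
    (per_sample, n_discarded)
        ``per_sample`` maps sample id -> Counter of reads with the barcode
        prefix stripped; reads whose prefix matches no barcode (including
        single-mismatch prefixes; there is no mismatch rescue) are counted
        as discarded.
    """
    lookup = {bc: sid for sid, bc in barcodes.items()}
    blen = barcodes.length
    per_sample: dict[str, Counter] = {sid: Counter() for sid in barcodes.barcodes}
    n_discarded = 0
    for read in reads:
        sid = lookup.get(read[:blen])
        if sid is None:
            n_discarded += 1
        else:
            per_sample[sid][read[blen:]] += 1
    return per_sample, n_discarded


def trim_adapter(insert: str, adapter: str, min_overlap: int = MIN_ADAPTER_OVERLAP) -> str:
    """Remove the suffix starting at the leftmost adapter match.

    The match is an exact occurrence of the adapter's first ``k`` nt, where
    ``k = min(len(adapter), remaining length)`` but at least ``min_overlap``.
    Reads without a match are returned unchanged (they are then rejected by
    the insert-length window downstream).
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    k = min(len(adapter), len(insert))
    while k >= min_overlap:
        pos = insert.find(adapter[:k])
        if pos != -1:
            return insert[:pos]
        k -= 1
    return insert


@dataclass
class AnnotatedReadSet:
    """Per-sample annotated read tallies.

    ``records`` maps sample id -> DataFrame with columns
    ``sequence, category, label, variant, count``; ``category`` is one of
    ``calibrator | mature | unannotated-genomic | discarded``; ``variant`` is
    an isomiR descriptor ("" for exact mature matches).
    """

    records: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.records)

    def category_tallies(self) -> pd.DataFrame:
        """Annotation-category read totals per sample (samples x category)."""
        rows = {}
        for sid, df in self.records.items():
            tally = df.groupby("category")["count"].sum()
            rows[sid] = tally.reindex(CATEGORIES, fill_value=0)
        return pd.DataFrame(rows).T.rename_axis("sample")

    def mature_counts(self, ref: MiRNAReference) -> CountMatrix:
        """Merged-mature CountMatrix (all reads per mature entry summed)."""
        cols = {}
        for sid, df in self.records.items():
            sub = df[df["category"] == "mature"]
            cols[sid] = sub.groupby("label")["count"].sum()
        mat = pd.DataFrame(cols).reindex(ref.names).fillna(0).astype(int)
        mat.columns = list(self.records)
        mat.index.name = None
        return CountMatrix(mat, "mature-merged")

    def calibrator_counts(self) -> pd.DataFrame:
        cols = {}
        for sid, df in self.records.items():
            sub = df[df["category"] == "calibrator"]
            cols[sid] = sub.groupby("label")["count"].sum()
        return pd.DataFrame(cols).fillna(0).astype(int)

    def variant_records(self) -> pd.DataFrame:
        """Read-level variant tallies: mirna, variant, sample, count."""
        rows = []
        for sid, df in self.records.items():
            sub = df[(df["category"] == "mature") & (df["variant"] != "")]
            for _, r in sub.iterrows():
                rows.append(
                    {
                        "mirna": r["label"],
                        "variant": r["variant"],
                        "sample": sid,
                        "count": int(r["count"]),
                    }
                )
        return pd.DataFrame(rows, columns=["mirna", "variant", "sample", "count"])

    def unannotated_reads(self) -> pd.DataFrame:
        """Genome-matching unannotated tallies: sequence, sample, count."""
        rows = []
        for sid, df in self.records.items():
            sub = df[df["category"] == "unannotated-genomic"]
            for _, r in sub.iterrows():
                rows.append(
                    {"sequence": r["sequence"], "sample": sid, "count": int(r["count"])}
                )
        return pd.DataFrame(rows, columns=["sequence", "sample", "count"])


class _Annotator:
    """Classify one insert against calibrators, matures and the genome."""

    def __init__(self, ref, calibrators, genome, abundance=None):
        if ref.table["sequence"].duplicated().any():  # defensive; ref validates too
            raise ValueError("reference sequences must be unique")
        self.mature_exact = ref.seq_to_name
        self.matures = list(zip(ref.table["name"], ref.table["sequence"]))
        self.cal_exact = calibrators.seq_to_name if calibrators is not None else {}
        self.genome = genome or ""
        self.genome_rc = _revcomp(self.genome) if genome else ""
        # tie-break rank: higher baseline abundance wins, then name order
        self.rank = {
            name: (-(abundance or {}).get(name, 0), name) for name, _ in self.matures
        }

    def _fuzzy_mature(self, seq: str):
        """Best non-exact mature match within the edit tolerance.

        Categories are disjoint by insert length relative to the mature:
        equal length -> <=1 substitution; shorter -> end trims within 2 nt per
        end; longer by <=3 -> untemplated 3' additions.  Ties between distinct
        matures at equal edit cost go to the higher-abundance mature.
        """
        candidates = []  # (edit_cost, rank, name, descriptor)
        for name, mat in self.matures:
            d = len(seq) - len(mat)
            if d == 0:
                mism = [i for i, (a, b) in enumerate(zip(seq, mat)) if a != b]
                if len(mism) == 1:
                    i = mism[0]
                    desc = f"p{i + 1}{mat[i]}>{seq[i]}"
                    candidates.append((1, self.rank[name], name, desc))
            elif d < 0:
                for a in range(0, 3):
                    b = len(mat) - len(seq) - a
                    if 0 <= b <= 2 and mat[a : len(mat) - b] == seq:
                        candidates.append((a + b, self.rank[name], name, f"5p-{a}|3p-{b}"))
                        break
            elif d <= 3:
                if seq.startswith(mat):
                    candidates.append((d, self.rank[name], name, f"3p+{seq[len(mat):]}"))
        if not candidates:
            return None
        candidates.sort()
        _, _, name, desc = candidates[0]
        return name, desc

    def classify(self, seq: str):
        """Return (category, label, variant descriptor)."""
        if not MIN_INSERT <= len(seq) <= MAX_INSERT:
            return "discarded", "", ""
        if seq in self.cal_exact:
            return "calibrator", self.cal_exact[seq], ""
        if seq in self.mature_exact:
            return "mature", self.mature_exact[seq], ""
        hit = self._fuzzy_mature(seq)
        if hit is not None:
            return "mature", hit[0], hit[1]
        if self.genome and (seq in self.genome or seq in self.genome_rc):
            return "unannotated-genomic", "", ""
        return "discarded", "", ""


def annotate(
    per_sample_inserts: dict,
    ref: MiRNAReference,
    calibrators: CalibratorManifest | None = None,
    genome: str | None = None,
) -> AnnotatedReadSet:
    """Annotate trimmed inserts for every sample.

    Parameters
    ----------
    per_sample_inserts : dict
        sample id -> Counter (or mapping) of trimmed insert -> read count.
    ref, calibrators, genome
        Catalogue, spike-in manifest and genome string for the
        unannotated-genomic class.

    Notes
    -----
    Tie-breaking between distinct matures at equal edit distance uses
    baseline abundance measured as the global exact-match tally over all
    samples (computed in a first pass), which keeps annotation deterministic
    and independent of read input order.
    """
    exact = ref.seq_to_name
    abundance: Counter = Counter()
    for inserts in per_sample_inserts.values():
        for seq, n in inserts.items():
            name = exact.get(seq)
            if name is not None:
                abundance[name] += n

    annotator = _Annotator(ref, calibrators, genome, abundance=dict(abundance))
    records = {}
    for sid, inserts in per_sample_inserts.items():
        rows = []
        for seq in sorted(inserts):
            cat, label, variant = annotator.classify(seq)
            rows.append(
                {
                    "sequence": seq,
                    "category": cat,
                    "label": label,
                    "variant": variant,
                    "count": int(inserts[seq]),
                }
            )
        records[sid] = pd.DataFrame(
            rows, columns=["sequence", "category", "label", "variant", "count"]
        )
    return AnnotatedReadSet(records)


def process_lane(
    fastq_path,
    barcodes: BarcodeMap,
    ref: MiRNAReference,
    adapter: str,
    calibrators: CalibratorManifest | None = None,
    genome: str | None = None,
):
    """Full stage: demultiplex -> trim -> annotate one FASTQ lane.

    Returns ``(AnnotatedReadSet, stats)`` where stats holds the demultiplexed
    and discarded read totals.  Count conservation holds per sample:
    annotated + unannotated + discarded reads equal the demultiplexed total.
    """
    reads = read_fastq_sequences(fastq_path)
    per_sample, n_unmatched = demultiplex(reads, barcodes)
    trimmed = {}
    for sid, counter in per_sample.items():
        out: Counter = Counter()
        for seq, n in counter.items():
            out[trim_adapter(seq, adapter)] += n
        trimmed[sid] = out
    annotated = annotate(trimmed, ref, calibrators, genome)
    stats = {
        "total_reads": len(reads),
        "unmatched_barcode": n_unmatched,
        "demultiplexed": {sid: sum(c.values()) for sid, c in per_sample.items()},
    }
    return annotated, stats
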