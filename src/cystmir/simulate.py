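"""Synthetic-data generator: every pipeline input with known ground truth.

Emulates a multiplexed small-RNA cDNA library study of two specimen groups
(e.g. ADPKD vs normal/CKD): a miRNA reference with multicopy, cistron-cluster
and sequence-family structure; negative-binomial counts with planted log2
fold changes; barcoded raw reads carrying a 3' adapter; spike-in calibrator
reads anchored to a planted molar miRNA content; planted sequence variants
(isomiR-like substitutions); and unannotated genome-matching decoy sequences
for the novel-miRNA mining stage.

All randomness flows from a single root seed through named substreams, so an
identical configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cystmir.profiles import CountMatrix
from cystmir.reference import BarcodeMap, CalibratorManifest, MiRNAReference

_NT = np.array(list("ACGT"))

# named substreams off the root seed
_STREAM_REFERENCE = 1
_STREAM_COUNTS = 2
_STREAM_READS = 3
_STREAM_VARIANTS = 4


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults mirror the profiled study arms: groups of 8-20 samples, miRNA
    library totals around 5e5 reads, NB dispersion 0.2 (typical biological
    variability for primary cultures / patient specimens), and a planted
    molar miRNA content of 5.8 fmol per ug input total RNA.
    """

    seed: int = 0
    n_samples_per_group: int = 10
    n_mirna: int = 30
    n_clusters: int = 12
    mean_library_size: int = 500_000
    dispersion: float = 0.2
    planted_log2fc: dict = field(default_factory=dict)
    baseline_cpm: dict = field(default_factory=dict)
    barcode_length: int = 5
    adapter_sequence: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length: int = 50
    n_calibrators: int = 3
    calibrator_fmol: float = 0.5
    mirna_fmol_per_ug: float = 5.8
    input_ug: float = 5.0
    variant_effect: dict = field(default_factory=dict)
    variant_base_freq: float = 0.2
    decoy_rpm: dict = field(default_factory=dict)
    group_labels: tuple = ("normal", "ADPKD")

    def __post_init__(self) -> None:
        if self.n_mirna < 3:
            raise ValueError(
                "n_mirna must be >= 3 to host multicopy, cistron and family groupings"
            )
        if not 1 <= self.n_clusters < self.n_mirna:
            raise ValueError("need 1 <= n_clusters < n_mirna")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.mean_library_size <= 0:
            raise ValueError("mean_library_size must be positive")
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")
        if self.calibrator_fmol <= 0:
            raise ValueError("calibrator_fmol must be positive")
        if set(self.adapter_sequence) - set("ACGT"):
            raise ValueError("adapter must be uppercase ACGT")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _annotation_conflict(a: str, b: str) -> bool:
    """True if reads derived from ``a`` (exact, <=1 substitution, end trims
    within 2 nt, <=3 untemplated 3' additions) could be attributed to ``b``.

    Keeping catalogue sequences pairwise non-conflicting guarantees that the
    annotation stage assigns generator reads unambiguously.
    """
    if abs(len(a) - len(b)) > 5:
        return False
    if len(a) == len(b):
        return _hamming(a, b) <= 3
    short, long_ = (a, b) if len(a) < len(b) else (b, a)
    for start in range(0, 3):
        for stop_trim in range(0, 4):
            window = long_[start : len(long_) - stop_trim]
            if len(window) == len(short) and _hamming(window, short) <= 2:
                return True
    return False


def _draw_safe_seq(rng, existing, adapter, lengths=(21, 22, 23), max_tries=200) -> str:
    adapter_seed = adapter[:6]
    for _ in range(max_tries):
        seq = _random_seq(rng, int(rng.choice(lengths)))
        if adapter_seed in seq:
            continue
        if any(_annotation_conflict(seq, e) for e in existing):
            continue
        return seq
    raise RuntimeError("could not draw an annotation-safe sequence")


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def make_reference(cfg: SimulationConfig) -> MiRNAReference:
    """Generate a miRNA catalogue with the three grouping structures.

    Guarantees at least one multicopy mature entry (identical mature sequence
    at two loci, merged under a ``(2)`` name), one cistron cluster with >= 2
    members, and one sequence family whose two members differ by exactly two
    substitutions.  All mature sequences are 19-25 nt, mutually outside the
    annotation edit tolerance, and unique.
    """
    rng = cfg.rng(_STREAM_REFERENCE)
    n = cfg.n_mirna
    seqs: list[str] = []
    for _ in range(n):
        seqs.append(_draw_safe_seq(rng, seqs, cfg.adapter_sequence))

    # sequence family: mature 1 becomes a 2-substitution sibling of mature 0
    fam_seq = None
    for _ in range(200):
        base = list(seqs[0])
        pos = rng.choice(len(base), size=2, replace=False)
        cand = base[:]
        for p in pos:
            cand[p] = str(rng.choice([c for c in "ACGT" if c != base[p]]))
        cand = "".join(cand)
        others = [s for i, s in enumerate(seqs) if i not in (0, 1)]
        if cfg.adapter_sequence[:6] not in cand and not any(
            _annotation_conflict(cand, o) for o in others
        ):
            fam_seq = cand
            break
    if fam_seq is None:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not place sequence-family sibling")
    seqs[1] = fam_seq

    base_names = [f"miR-s{i + 1:02d}" for i in range(n)]
    names = list(base_names)
    copy_groups = list(base_names)
    n_copies = [1] * n
    # multicopy: mature at index 2 encoded at two loci, merged "(2)" entry
    multi = 2
    names[multi] = f"{base_names[multi]}-1(2)"
    copy_groups[multi] = names[multi]
    n_copies[multi] = 2

    # contiguous cistron-cluster blocks; block 0 always has >= 2 members
    sizes = np.full(cfg.n_clusters, n // cfg.n_clusters, dtype=int)
    sizes[: n % cfg.n_clusters] += 1
    if sizes[0] < 2:  # possible only when n == n_clusters, excluded by config
        raise ValueError("cannot host a multi-member cistron cluster")
    clusters = []
    idx = 0
    for size in sizes:
        first = base_names[idx].replace("miR-", "mir-")
        clusters.extend([f"cluster-{first}({size})"] * size)
        idx += size

    families = [f"seqfam-{bn}(1)" for bn in base_names]
    fam_name = f"seqfam-{base_names[0]}(2)"
    families[0] = families[1] = fam_name

    table = pd.DataFrame(
        {
            "name": names,
            "sequence": seqs,
            "copy_group": copy_groups,
            "n_copies": n_copies,
            "cluster": clusters,
            "family": families,
        }
    )
    return MiRNAReference(table)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(cfg: SimulationConfig, ref: MiRNAReference):
    """Draw a mature-merged NB count matrix with planted fold changes.

    For unit g and sample i, ``y_gi ~ NB(mean = s_i * q_g * 2**(beta_g * group_i),
    dispersion phi)`` with ``var = mean + phi * mean**2``.  ``s_i`` is a
    library-size factor log-uniform within 2-fold of ``mean_library_size``;
    ``q_g`` are baseline relative abundances (log-normal, normalized), pinned
    to ``baseline_cpm / 1e6`` for units named there; ``beta_g`` is the planted
    log2 fold change (0 unless named in ``planted_log2fc``).

    Returns
    -------
    (CountMatrix, samples, truth)
        ``samples``: DataFrame sample/group/sex/lib_factor.
        ``truth``: DataFrame unit/q/log2fc.
    """
    rng = cfg.rng(_STREAM_COUNTS)
    units = ref.names
    unknown = set(cfg.planted_log2fc) - set(units)
    if unknown:
        raise ValueError(f"planted_log2fc names unknown units: {sorted(unknown)}")
    unknown = set(cfg.baseline_cpm) - set(units)
    if unknown:
        raise ValueError(f"baseline_cpm names unknown units: {sorted(unknown)}")

    g = len(units)
    q = rng.lognormal(mean=0.0, sigma=2.0, size=g)
    q /= q.sum()
    pinned = np.array([u in cfg.baseline_cpm for u in units])
    if pinned.any():
        fixed = np.array([cfg.baseline_cpm.get(u, 0.0) for u in units]) / 1e6
        if fixed.sum() >= 1.0:
            raise ValueError("pinned baseline CPM exceeds the library")
        q[~pinned] *= (1.0 - fixed[pinned].sum()) / q[~pinned].sum()
        q[pinned] = fixed[pinned]

    beta = np.array([cfg.planted_log2fc.get(u, 0.0) for u in units])

    n_per = cfg.n_samples_per_group
    labels = [cfg.group_labels[0]] * n_per + [cfg.group_labels[1]] * n_per
    sample_ids = [
        f"{lab}_{k + 1:02d}" for lab in cfg.group_labels for k in range(n_per)
    ]
    is_case = np.array([0] * n_per + [1] * n_per)
    sex = np.array(["F", "M"] * n_per)[: 2 * n_per]  # alternating within groups
    s = cfg.mean_library_size * 2.0 ** rng.uniform(-1, 1, size=2 * n_per)

    mean = s[None, :] * q[:, None] * 2.0 ** (beta[:, None] * is_case[None, :])
    r = 1.0 / cfg.dispersion
    p = 1.0 / (1.0 + cfg.dispersion * mean)
    y = rng.negative_binomial(r, p)

    counts = CountMatrix(
        pd.DataFrame(y, index=units, columns=sample_ids), "mature-merged"
    )
    samples = pd.DataFrame(
        {"sample": sample_ids, "group": labels, "sex": sex, "lib_factor": s}
    ).set_index("sample")
    truth = pd.DataFrame({"unit": units, "q": q, "log2fc": beta}).set_index("unit")
    return counts, samples, truth


# ---------------------------------------------------------------------------
# raw reads
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReads:
    """Paths and ground-truth ledgers for one synthesized lane."""

    fastq: str
    barcode_map: BarcodeMap
    calibrators: CalibratorManifest
    genome_path: str
    reference_path: str
    mature_ledger: pd.DataFrame       # unit x sample planted read counts
    variant_ledger: pd.DataFrame      # unit, variant, sample, count
    calibrator_ledger: pd.DataFrame   # calibrator x sample read counts
    decoy_ledger: pd.DataFrame        # decoy name, sequence, sample, count
    paths: dict = field(default_factory=dict)


def _parse_variant_id(vid: str):
    unit, pos, alt = vid.split("|")
    return unit, int(pos), alt


def _make_barcodes(rng, samples, length) -> BarcodeMap:
    codes: list[str] = []
    while len(codes) < len(samples):
        cand = _random_seq(rng, length)
        if all(_hamming(cand, c) >= 2 for c in codes):
            codes.append(cand)
    return BarcodeMap(dict(zip(samples, codes)))


def synthesize_reads(
    cfg: SimulationConfig,
    ref: MiRNAReference,
    counts: CountMatrix,
    samples: pd.DataFrame,
    out_dir: str,
) -> SimulatedReads:
    """Write one FASTQ lane of barcoded reads realizing a count matrix exactly.

    Each read is ``barcode + insert + 3' adapter`` truncated to the read
    length; inserts are mature sequences (a planted fraction mutated into
    sequence variants), calibrator oligos, or genome-matching decoys.  The
    per-sample per-unit mature read tallies equal ``counts`` exactly, so the
    processing stages can be validated by round-trip conservation.
    """
    rng = cfg.rng(_STREAM_READS)
    os.makedirs(out_dir, exist_ok=True)
    sample_ids = list(counts.samples)
    if list(samples.index) != sample_ids:
        raise ValueError("sample table and count matrix disagree on samples")

    barcode_map = _make_barcodes(rng, sample_ids, cfg.barcode_length)
    seq_by_name = dict(zip(ref.table["name"], ref.table["sequence"]))

    # calibrators: equimolar spike-ins, sequences outside the catalogue
    cal_seqs: list[str] = []
    existing = list(ref.table["sequence"])
    for _ in range(cfg.n_calibrators):
        s = _draw_safe_seq(rng, existing + cal_seqs, cfg.adapter_sequence, (21, 22))
        cal_seqs.append(s)
    calibrators = CalibratorManifest(
        pd.DataFrame(
            {
                "name": [f"cal-{i + 1:02d}" for i in range(cfg.n_calibrators)],
                "sequence": cal_seqs,
                "fmol": cfg.calibrator_fmol,
            }
        )
    )

    # decoys: 21-23 nt, genome-matching, outside annotation tolerance of any
    # mature or calibrator, so they survive annotation as unannotated-genomic
    decoy_names = list(cfg.decoy_rpm)
    decoy_seqs = {}
    for name in decoy_names:
        decoy_seqs[name] = _draw_safe_seq(
            rng, existing + cal_seqs + list(decoy_seqs.values()), cfg.adapter_sequence
        )

    # toy genome: random background with the decoys embedded
    background = _random_seq(rng, 2000)
    genome_seq = background
    for name in decoy_names:
        genome_seq += _random_seq(rng, 50) + decoy_seqs[name]
    genome_seq += _random_seq(rng, 50)

    # planted variants: at most one per unit, annotation-safe substitution
    variants_by_unit: dict[str, tuple[str, str]] = {}
    for vid in cfg.variant_effect:
        unit, pos, alt = _parse_variant_id(vid)
        if unit not in seq_by_name:
            raise ValueError(f"variant id names unknown unit: {vid}")
        if unit in variants_by_unit:
            raise ValueError(f"multiple planted variants for unit {unit}")
        mature = seq_by_name[unit]
        if not 1 <= pos <= len(mature):
            raise ValueError(f"variant position out of range: {vid}")
        if alt == mature[pos - 1] or alt not in "ACGT":
            raise ValueError(f"invalid variant base in {vid}")
        mutated = mature[: pos - 1] + alt + mature[pos:]
        others = [s for nm, s in seq_by_name.items() if nm != unit] + cal_seqs
        if any(len(o) == len(mutated) and _hamming(o, mutated) <= 1 for o in others):
            raise ValueError(f"planted variant {vid} collides with another sequence")
        variants_by_unit[unit] = (vid, mutated)

    is_case = (samples["group"] == cfg.group_labels[1]).astype(int)
    totals = counts.totals
    mirna_fmol = cfg.mirna_fmol_per_ug * cfg.input_ug

    inserts: list[str] = []
    owners: list[str] = []  # sample each read belongs to (for the ledger only)
    variant_rows = []
    cal_counts = pd.DataFrame(
        0, index=calibrators.table["name"], columns=sample_ids, dtype=int
    )
    decoy_rows = []

    for sid in sample_ids:
        bc = barcode_map.barcodes[sid]
        case = int(is_case[sid])
        for unit, y in counts.counts[sid].items():
            y = int(y)
            if y == 0:
                continue
            mature = seq_by_name[unit]
            n_var = 0
            if unit in variants_by_unit:
                vid, mutated = variants_by_unit[unit]
                freq = float(
                    np.clip(
                        cfg.variant_base_freq + cfg.variant_effect[vid] * case, 0, 1
                    )
                )
                n_var = int(rng.binomial(y, freq))
                if n_var:
                    variant_rows.append(
                        {"unit": unit, "variant": vid, "sample": sid, "count": n_var}
                    )
                inserts.extend([mutated] * n_var)
                owners.extend([sid] * n_var)
            inserts.extend([mature] * (y - n_var))
            owners.extend([sid] * (y - n_var))
        # calibrator reads anchored to the planted molar content
        expected = totals[sid] * calibrators.total_fmol / mirna_fmol
        for cname in calibrators.table["name"]:
            k = int(rng.poisson(expected / cfg.n_calibrators))
            cal_counts.loc[cname, sid] = k
            cseq = calibrators.table.set_index("name").loc[cname, "sequence"]
            inserts.extend([cseq] * k)
            owners.extend([sid] * k)
        for name, rpm in cfg.decoy_rpm.items():
            k = int(round(rpm * totals[sid] / 1e6))
            decoy_rows.append(
                {"name": name, "sequence": decoy_seqs[name], "sample": sid, "count": k}
            )
            inserts.extend([decoy_seqs[name]] * k)
            owners.extend([sid] * k)

    order = rng.permutation(len(inserts))
    fastq_path = os.path.join(out_dir, "lane1.fastq")
    bc_of = {sid: barcode_map.barcodes[sid] for sid in sample_ids}
    with open(fastq_path, "w") as fh:
        for ridx, i in enumerate(order):
            read = (bc_of[owners[i]] + inserts[i] + cfg.adapter_sequence)[
                : cfg.read_length
            ]
            fh.write(f"@r{ridx + 1:07d}\n{read}\n+\n{'I' * len(read)}\n")

    paths = {
        "fastq": fastq_path,
        "reference": os.path.join(out_dir, "reference.tsv"),
        "barcodes": os.path.join(out_dir, "barcodes.tsv"),
        "calibrators": os.path.join(out_dir, "calibrators.tsv"),
        "genome": os.path.join(out_dir, "genome.fa"),
        "truth_counts": os.path.join(out_dir, "truth_counts.tsv"),
        "truth_variants": os.path.join(out_dir, "truth_variants.tsv"),
        "truth_calibrators": os.path.join(out_dir, "truth_calibrators.tsv"),
        "truth_decoys": os.path.join(out_dir, "truth_decoys.tsv"),
    }
    ref.to_tsv(paths["reference"])
    barcode_map.to_tsv(paths["barcodes"])
    calibrators.to_tsv(paths["calibrators"])
    with open(paths["genome"], "w") as fh:
        fh.write(">toy_genome\n")
        for i in range(0, len(genome_seq), 70):
            fh.write(genome_seq[i : i + 70] + "\n")
    counts.to_tsv(paths["truth_counts"])
    variant_ledger = pd.DataFrame(
        variant_rows, columns=["unit", "variant", "sample", "count"]
    )
    variant_ledger.to_csv(paths["truth_variants"], sep="\t", index=False)
    cal_counts.rename_axis("calibrator").to_csv(paths["truth_calibrators"], sep="\t")
    decoy_ledger = pd.DataFrame(
        decoy_rows, columns=["name", "sequence", "sample", "count"]
    )
    decoy_ledger.to_csv(paths["truth_decoys"], sep="\t", index=False)

    return SimulatedReads(
        fastq=fastq_path,
        barcode_map=barcode_map,
        calibrators=calibrators,
        genome_path=paths["genome"],
        reference_path=paths["reference"],
        mature_ledger=counts.counts.copy(),
        variant_ledger=variant_ledger,
        calibrator_ledger=cal_counts,
        decoy_ledger=decoy_ledger,
        paths=paths,
    )


# ---------------------------------------------------------------------------
# variant frequency tables (direct emulation of the tabulated study layout)
# ---------------------------------------------------------------------------

def simulate_variant_table(
    seed: int,
    n_case: int = 10,
    n_control: int = 8,
    n_variants: int = 138,
    n_shifted: int = 9,
    effect_sd_multiple: float = 3.0,
    base_freq_range: tuple = (0.02, 0.30),
    noise_cv: float = 0.25,
    obs_prob_shifted: tuple = (0.75, 1.0),
    obs_prob_null: tuple = (0.05, 0.5),
):
    """Per-(miRNA, variant) relative-frequency table with planted group shifts.

    Emulates a profiled variant catalogue: ~138 variants
    observed across two specimen groups, of which a handful carry a true
    group shift.  Frequencies are Gaussian around a per-variant baseline
    (truncated to [0, 1]); shifted variants gain ``effect_sd_multiple`` noise
    standard deviations in the case group (all shifts upward, matching the
    above-median scoring rule).  Cells are missing at random per variant,
    emulating (miRNA, sample) pairs below the read-depth floor; disease-
    associated variants are broadly quantifiable while the bulk of the
    catalogue sits near that floor — the regime in which an uncorrected
    screen of ~138 variants yields on the order of ten selections, as in the
    profiled study.

    Returns ``(table, labels, shifted_ids)`` where ``table`` has a
    (miRNA, variant) MultiIndex and one column per sample, and ``labels`` is
    a 0/1 Series (1 = case).
    """
    rng = np.random.default_rng([int(seed), _STREAM_VARIANTS])
    samples = [f"ctrl_{i + 1:02d}" for i in range(n_control)] + [
        f"case_{i + 1:02d}" for i in range(n_case)
    ]
    labels = pd.Series([0] * n_control + [1] * n_case, index=samples)

    base = rng.uniform(*base_freq_range, size=n_variants)
    sd = noise_cv * base
    shifted = rng.choice(n_variants, size=n_shifted, replace=False)
    shift = np.zeros(n_variants)
    shift[shifted] = effect_sd_multiple * sd[shifted]

    freq = base[:, None] + sd[:, None] * rng.standard_normal((n_variants, len(samples)))
    freq += shift[:, None] * labels.values[None, :]
    freq = np.clip(freq, 0.0, 1.0)

    is_shifted = np.zeros(n_variants, dtype=bool)
    is_shifted[shifted] = True
    p_obs = np.where(
        is_shifted,
        rng.uniform(*obs_prob_shifted, size=n_variants),
        rng.uniform(*obs_prob_null, size=n_variants),
    )
    mask = rng.random((n_variants, len(samples))) > p_obs[:, None]
    freq[mask] = np.nan

    index = pd.MultiIndex.from_tuples(
        [(f"miR-v{i + 1:03d}", f"miR-v{i + 1:03d}|10|G") for i in range(n_variants)],
        names=["mirna", "variant"],
    )
    table = pd.DataFrame(freq, index=index, columns=samples)
    shifted_ids = [table.index[i] for i in sorted(shifted)]
    return table, labels, shifted_ids
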