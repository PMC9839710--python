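"""Synthetic ChIATAC-style data with known ground truth.

Generates toy genomes, a planted 3D-epigenome truth set (open-chromatin
peaks and loops anchored at them, spans log-uniform on 10 kb - 1 Mb),
labeled PET collections drawn from a signal/background/self-ligation/trans
mixture with PCR duplicates, and paired-end FASTQ whose fragments carry the
``tag - 19-nt bridge linker - tag`` junction structure of the assay.

Every generator is deterministic for a fixed seed. Labels let downstream
tests measure recovery against truth rather than against a real dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .linker_pets import LINKER, PET, Tag, ExtractResult, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ToyGenome:
    """A small random reference: named chromosomes with A/C/G/T sequence."""

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chroms)) != len(self.chroms):
            raise ValueError("chromosome names must be unique")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.chroms[chrom]
        if start < 0 or end > len(seq) or end <= start:
            raise ValueError(f"bad interval {chrom}:{start}-{end}")
        return seq[start:end]


def make_genome(lengths, seed: int = 0, names=None) -> ToyGenome:
    """Uniform-random toy genome with the given chromosome lengths (bp)."""
    lengths = list(lengths)
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    if names is None:
        names = [f"chr{i + 1}" for i in range(len(lengths))]
    rng = np.random.default_rng(seed)
    chroms = {}
    for name, length in zip(names, lengths):
        arr = rng.choice(_BASES, size=length)
        chroms[name] = arr.tobytes().decode("ascii")
    return ToyGenome(chroms)


@dataclass(frozen=True)
class TruthPeak:
    chrom: str
    start: int
    end: int
    weight: float  # relative enrichment weight, > 0


@dataclass(frozen=True)
class TruthLoop:
    chrom: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    weight: float
    support: str  # "both" | "one" | "none": anchors on truth peaks

    @property
    def span(self) -> float:
        return abs((self.start_b + self.end_b) / 2 - (self.start_a + self.end_a) / 2)


@dataclass
class NoiseParams:
    """Mixture weights of the non-signal PET classes plus decay/dup rates.

    The signal fraction is the remainder 1 - trans - self - background.
    ``decay_exponent`` is the power-law slope of the cis background span
    distribution (contact frequency ~ span**-exponent).
    """

    trans_frac: float = 0.05
    self_frac: float = 0.15
    background_frac: float = 0.35
    dup_rate: float = 0.10
    decay_exponent: float = 1.0

    @property
    def signal_frac(self) -> float:
        return 1.0 - self.trans_frac - self.self_frac - self.background_frac

    def validate(self) -> None:
        if min(self.trans_frac, self.self_frac, self.background_frac, self.dup_rate) < 0:
            raise ValueError("noise fractions must be non-negative")
        if self.signal_frac < -1e-12:
            raise ValueError("noise fractions sum to more than 1")
        if self.dup_rate >= 1:
            raise ValueError("dup_rate must be < 1")


@dataclass
class TruthSet:
    """Planted peaks and loops plus the noise model and generator seed."""

    peaks: list[TruthPeak]
    loops: list[TruthLoop]
    noise: NoiseParams
    seed: int


#: loop span sampling bounds (bp): log-uniform across the observed range of
#: intra-chromosomal loop spans, roughly 10 kb to 1 Mb.
SPAN_RANGE = (10_000, 1_000_000)


def _sample_span(rng, lo: float, hi: float) -> int:
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def make_truth(
    genome: ToyGenome,
    n_peaks: int,
    n_loops: int,
    span_range: tuple[float, float] = SPAN_RANGE,
    support_fractions: dict[str, float] | None = None,
    anchor_width: int = 500,
    noise: NoiseParams | None = None,
    seed: int = 0,
    max_tries: int = 200,
    clearance: int = 2000,
) -> TruthSet:
    """Plant peaks and peak-anchored loops on a toy genome.

    Loops are placed first with spans log-uniform on ``span_range``
    (truncated per chromosome); peaks are then planted exactly on the
    anchors of "both"-supported loops, on one anchor of "one"-supported
    loops, and independently elsewhere until ``n_peaks`` are placed.
    ``support_fractions`` gives the both/one/none label proportions
    (default: both=0.6, one=0.2, none=0.2). Unsupported anchors are kept at
    least ``clearance`` bp away from every planted peak so the support
    labels are unambiguous. Deterministic for fixed seed.
    """
    if support_fractions is None:
        support_fractions = {"both": 0.6, "one": 0.2, "none": 0.2}
    fr = {k: support_fractions.get(k, 0.0) for k in ("both", "one", "none")}
    if abs(sum(fr.values()) - 1.0) > 1e-9:
        raise ValueError("support_fractions must sum to 1")
    rng = np.random.default_rng(seed)
    names = list(genome.chroms)
    lens = np.array([genome.lengths[c] for c in names], dtype=float)
    if noise is None:
        noise = NoiseParams(trans_frac=0.05 if len(names) > 1 else 0.0)
    noise.validate()
    w = anchor_width
    labels = rng.choice(["both", "one", "none"], size=n_loops, p=[fr[k] for k in ("both", "one", "none")])
    loops: list[TruthLoop] = []
    peaks: list[TruthPeak] = []
    forbidden: list[tuple[str, int, int]] = []  # unsupported anchors + clearance

    def clash(chrom: str, s: int, e: int, regions, pad: int = 0) -> bool:
        return any(c == chrom and r_s - pad < e and s < r_e + pad for c, r_s, r_e in regions)

    peak_ivs = lambda: [(p.chrom, p.start, p.end) for p in peaks]
    for lab in labels:
        for _ in range(max_tries):
            ci = rng.choice(len(names), p=lens / lens.sum())
            L = int(lens[ci])
            span = _sample_span(rng, span_range[0], min(span_range[1], 0.8 * L))
            if span + 2 * w >= L:
                continue
            mid_a = int(rng.integers(w, L - span - w))
            mid_b = mid_a + span
            iv_a = (mid_a - w // 2, mid_a + w - w // 2)
            iv_b = (mid_b - w // 2, mid_b + w - w // 2)
            if lab == "both":
                on_peak, off_peak = [iv_a, iv_b], []
            elif lab == "one":
                on_peak, off_peak = ([iv_a], [iv_b]) if rng.random() < 0.5 else ([iv_b], [iv_a])
            else:
                on_peak, off_peak = [], [iv_a, iv_b]
            # supported anchors stay clear of unsupported ones and vice versa
            if any(clash(names[ci], s, e, forbidden, clearance) for s, e in on_peak):
                continue
            if any(clash(names[ci], s, e, peak_ivs(), clearance) for s, e in off_peak):
                continue
            break
        else:
            raise RuntimeError("could not place loop within genome after bounded retries")
        loops.append(
            TruthLoop(names[ci], iv_a[0], iv_a[1], iv_b[0], iv_b[1],
                      weight=float(rng.lognormal(0.0, 0.5)), support=str(lab))
        )
        for s, e in on_peak:
            peaks.append(TruthPeak(names[ci], s, e, float(rng.lognormal(0.0, 0.5))))
        for s, e in off_peak:
            forbidden.append((names[ci], s, e))
    if len(peaks) > n_peaks:
        raise ValueError(
            f"n_peaks={n_peaks} too small for the anchor-supported loops ({len(peaks)} anchor peaks)"
        )
    # independent peaks: non-overlapping, clear of unsupported anchors
    tries = 0
    while len(peaks) < n_peaks:
        tries += 1
        if tries > max_tries * n_peaks:
            raise RuntimeError("could not place independent peaks after bounded retries")
        ci = rng.choice(len(names), p=lens / lens.sum())
        L = int(lens[ci])
        s = int(rng.integers(0, L - w))
        if clash(names[ci], s, s + w, peak_ivs()) or clash(names[ci], s, s + w, forbidden, clearance):
            continue
        peaks.append(TruthPeak(names[ci], s, s + w, float(rng.lognormal(0.0, 0.5))))
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return TruthSet(peaks=peaks, loops=loops, noise=noise, seed=int(seed))


@dataclass(frozen=True)
class LabeledPET:
    """A PET plus its generative truth label.

    label is one of ``loop_signal``, ``background``, ``self_ligation``,
    ``trans``, ``duplicate``; for duplicates ``dup_of`` indexes the copied
    PET and ``loop_id`` carries through from the source.
    """

    pet: PET
    label: str
    loop_id: int | None = None
    dup_of: int | None = None


def _mk_pet(chrom_a, sa, la, chrom_b, sb, lb, idx) -> PET:
    a = Tag(read_id=f"pet{idx:08d}", mate=0, side="A", chrom=chrom_a, start=int(sa), end=int(sa + la))
    b = Tag(read_id=f"pet{idx:08d}", mate=1, side="B", chrom=chrom_b, start=int(sb), end=int(sb + lb))
    if (a.chrom, a.start) > (b.chrom, b.start):
        a, b = (
            Tag(read_id=a.read_id, mate=0, side="A", chrom=b.chrom, start=b.start, end=b.end),
            Tag(read_id=a.read_id, mate=1, side="B", chrom=a.chrom, start=a.start, end=a.end),
        )
    return PET(tag_a=a, tag_b=b)


def simulate_pets(
    truth: TruthSet,
    genome: ToyGenome,
    n_pets: int,
    tag_len_range: tuple[int, int] = (16, 80),
    seed: int = 0,
) -> list[LabeledPET]:
    """Draw a labeled PET collection from the truth set's mixture model.

    Each non-duplicate draw is loop signal (ends uniform within the loop's
    two anchors, loop chosen proportional to weight), cis background (span
    from a truncated power law with the configured decay exponent), a
    self-ligation product (span <= 8 kb by construction) or a trans contact;
    with probability ``dup_rate`` a draw is instead an exact coordinate copy
    of an earlier PET (a PCR duplicate).
    """
    if n_pets < 0:
        raise ValueError("n_pets must be >= 0")
    noise = truth.noise
    noise.validate()
    rng = np.random.default_rng(seed)
    names = list(genome.chroms)
    lens = np.array([genome.lengths[c] for c in names], dtype=float)
    if noise.trans_frac > 0 and len(names) < 2:
        raise ValueError("trans_frac > 0 requires at least two chromosomes")
    loop_w = np.array([l.weight for l in truth.loops], dtype=float)
    if noise.signal_frac > 1e-12 and len(truth.loops) == 0:
        raise ValueError("signal fraction > 0 but the truth set has no loops")
    loop_p = loop_w / loop_w.sum() if len(loop_w) else None
    lo, hi = tag_len_range
    probs = np.array([noise.signal_frac, noise.background_frac, noise.self_frac, noise.trans_frac])
    probs = np.clip(probs, 0, None)
    probs = probs / probs.sum()
    out: list[LabeledPET] = []
    alpha = noise.decay_exponent

    def power_law_span(s_min: float, s_max: float) -> float:
        u = rng.random()
        if abs(alpha - 1.0) < 1e-9:
            return s_min * (s_max / s_min) ** u
        a1 = 1.0 - alpha
        return (s_min**a1 + u * (s_max**a1 - s_min**a1)) ** (1.0 / a1)

    for i in range(n_pets):
        if out and rng.random() < noise.dup_rate:
            j = int(rng.integers(0, len(out)))
            src = out[j]
            while src.label == "duplicate":
                src = out[src.dup_of]  # copy the original's coordinates
            p = src.pet
            pet = _mk_pet(p.tag_a.chrom, p.tag_a.start, p.tag_a.length,
                          p.tag_b.chrom, p.tag_b.start, p.tag_b.length, i)
            out.append(LabeledPET(pet, "duplicate", loop_id=src.loop_id, dup_of=j))
            continue
        la, lb = int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1))
        kind = rng.choice(4, p=probs)
        if kind == 0:  # loop signal
            li = int(rng.choice(len(truth.loops), p=loop_p))
            lp = truth.loops[li]
            sa = int(rng.integers(lp.start_a, max(lp.start_a + 1, lp.end_a - la)))
            sb = int(rng.integers(lp.start_b, max(lp.start_b + 1, lp.end_b - lb)))
            out.append(LabeledPET(_mk_pet(lp.chrom, sa, la, lp.chrom, sb, lb, i), "loop_signal", loop_id=li))
        elif kind == 1:  # cis distance-decay background
            ci = int(rng.choice(len(names), p=lens / lens.sum()))
            L = int(lens[ci])
            span = power_law_span(1000.0, max(2000.0, L / 2))
            sa = int(rng.integers(0, max(1, L - int(span) - lb - 1)))
            out.append(LabeledPET(_mk_pet(names[ci], sa, la, names[ci], sa + int(span), lb, i), "background"))
        elif kind == 2:  # self-ligation, midpoint span kept <= 8 kb
            ci = int(rng.choice(len(names), p=lens / lens.sum()))
            L = int(lens[ci])
            span = int(rng.integers(100, 8000 - hi))
            sa = int(rng.integers(0, L - span - lb - 1))
            out.append(LabeledPET(_mk_pet(names[ci], sa, la, names[ci], sa + span, lb, i), "self_ligation"))
        else:  # trans
            ca, cb = rng.choice(len(names), size=2, replace=False, p=lens / lens.sum())
            sa = int(rng.integers(0, lens[int(ca)] - la))
            sb = int(rng.integers(0, lens[int(cb)] - lb))
            out.append(LabeledPET(_mk_pet(names[int(ca)], sa, la, names[int(cb)], sb, lb, i), "trans"))
    return out


def simulate_tags(
    truth: TruthSet,
    genome: ToyGenome,
    n_tags: int,
    enrichment: float = 20.0,
    tag_len: int = 50,
    seed: int = 0,
) -> list[Tag]:
    """Draw single open-chromatin tags: peak bases ``enrichment``-fold denser.

    Emulates the one-dimensional accessibility component of the assay for
    peak-calling tests: each tag lands inside a truth peak with probability
    proportional to enrichment x peak bp, otherwise uniformly on the genome.
    """
    rng = np.random.default_rng(seed)
    names = list(genome.chroms)
    lens = np.array([genome.lengths[c] for c in names], dtype=float)
    peak_bp = sum(p.end - p.start for p in truth.peaks)
    g = lens.sum()
    p_peak = enrichment * peak_bp / (enrichment * peak_bp + (g - peak_bp)) if peak_bp else 0.0
    widths = np.array([p.end - p.start for p in truth.peaks], dtype=float)
    tags: list[Tag] = []
    for i in range(n_tags):
        if rng.random() < p_peak:
            pi = int(rng.choice(len(truth.peaks), p=widths / widths.sum()))
            pk = truth.peaks[pi]
            s = int(rng.integers(pk.start, max(pk.start + 1, pk.end - tag_len)))
            chrom = pk.chrom
        else:
            ci = int(rng.choice(len(names), p=lens / lens.sum()))
            chrom = names[ci]
            s = int(rng.integers(0, lens[ci] - tag_len))
        tags.append(Tag(read_id=f"tag{i:08d}", mate=0, side="A", chrom=chrom, start=s, end=s + tag_len))
    return tags


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class FastqRecord:
    name: str
    seq: str
    qual: str


def _inject_errors(seq: str, rng, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    pets: list[LabeledPET],
    genome: ToyGenome,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
):
    """Sequence each PET as a read pair over its linker-joined fragment.

    The fragment is ``seq(tagA) + 19-nt junction + seq(tagB)``, reverse
    complemented with probability 1/2 (ligation orientation); mate 1 reads
    from the fragment start and mate 2 from the reverse complement of its
    end, each up to ``read_len`` (shorter fragments yield shorter reads —
    adapters are not simulated). Substitution errors occur per base at
    ``error_rate``. Returns ``(read_pairs, truth_table)`` where
    ``read_pairs`` is a list of (FastqRecord, FastqRecord) and the table
    records per pair the truth tag coordinates, orientation and the linker
    junction offset within each mate (-1 when not fully contained).
    """
    min_tag = 16
    if read_len < len(LINKER) + min_tag:
        raise ValueError(f"read_len must be >= {len(LINKER) + min_tag}")
    # separate streams: fragment structure is invariant to the error model
    rng, err_rng = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)]
    pairs: list[tuple[FastqRecord, FastqRecord]] = []
    rows = []
    for idx, lp in enumerate(pets):
        a, b = lp.pet.tag_a, lp.pet.tag_b
        seq_a = genome.fetch(a.chrom, a.start, a.end)
        seq_b = genome.fetch(b.chrom, b.start, b.end)
        frag = seq_a + LINKER + seq_b
        flipped = bool(rng.random() < 0.5)
        if flipped:
            frag = revcomp(frag)
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        # junction offset: linker start within each mate, -1 if not fully in
        la, lb = len(seq_a), len(seq_b)
        if flipped:
            off1 = lb if lb + len(LINKER) <= len(r1) else -1
            off2 = la if la + len(LINKER) <= len(r2) else -1
        else:
            off1 = la if la + len(LINKER) <= len(r1) else -1
            off2 = lb if lb + len(LINKER) <= len(r2) else -1
        r1 = _inject_errors(r1, err_rng, error_rate)
        r2 = _inject_errors(r2, err_rng, error_rate)
        name = f"pet{idx:08d}"
        pairs.append(
            (FastqRecord(name + "/1", r1, "I" * len(r1)), FastqRecord(name + "/2", r2, "I" * len(r2)))
        )
        rows.append(
            dict(read_id=name, pet_index=idx, label=lp.label, loop_id=lp.loop_id,
                 chrom_a=a.chrom, start_a=a.start, end_a=a.end,
                 chrom_b=b.chrom, start_b=b.start, end_b=b.end,
                 flipped=flipped, junction_r1=off1, junction_r2=off2)
        )
    return pairs, pd.DataFrame(rows)


def assign_truth_coordinates(
    results: list[ExtractResult], truth_table: pd.DataFrame
) -> list[Tag]:
    """Map extracted tag fragments to genome coordinates via the truth table.

    Stands in for an aligner on synthetic data. Because mate 1 always starts
    at the fragment's leading edge and mate 2 at its trailing edge, an
    extracted A-side fragment of length l is the 3' portion of tag A
    (``[end_a - l, end_a)``) and a B-side fragment the 5' portion of tag B
    (``[start_b, start_b + l)``), in every flip/mate combination.
    """
    lookup = {
        rid: (ca, int(ea), cb, int(sb))
        for rid, ca, ea, cb, sb in zip(
            truth_table["read_id"], truth_table["chrom_a"], truth_table["end_a"],
            truth_table["chrom_b"], truth_table["start_b"],
        )
    }
    mapped: list[Tag] = []
    for res in results:
        row = lookup.get(res.read_id)
        if row is None:
            continue
        chrom_a, end_a, chrom_b, start_b = row
        for t in res.tags:
            l = len(t.seq)
            if t.side == "A":
                chrom, start, end = chrom_a, end_a - l, end_a
            else:
                chrom, start, end = chrom_b, start_b, start_b + l
            mapped.append(
                Tag(read_id=t.read_id, mate=t.mate, side=t.side, seq=t.seq,
                    chrom=str(chrom), start=start, end=end)
            )
    return mapped


# ---------------------------------------------------------------------------
# plain-text I/O: FASTQ, BED, BEDPE, TSV (0-based half-open throughout)
# ---------------------------------------------------------------------------

def write_fastq_pairs(pairs, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r1, r2 in pairs:
            f1.write(f"@{r1.name}\n{r1.seq}\n+\n{r1.qual}\n")
            f2.write(f"@{r2.name}\n{r2.seq}\n+\n{r2.qual}\n")


def read_fastq_pairs(path1, path2) -> list[tuple[FastqRecord, FastqRecord]]:
    def _read(path):
        recs = []
        with open(path) as f:
            lines = f.read().splitlines()
        for i in range(0, len(lines), 4):
            recs.append(FastqRecord(lines[i][1:], lines[i + 1], lines[i + 3]))
        return recs

    return list(zip(_read(path1), _read(path2)))


def write_truth(truth: TruthSet, pets: list[LabeledPET] | None, out_dir) -> None:
    """Serialize a truth set (and optional PET labels) to plain-text files.

    ``peaks.bed`` (BED6, score = weight), ``loops.bedpe`` (BEDPE + weight,
    support), ``pets.tsv`` and ``params.json`` (noise model + seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "peaks.bed", "w") as f:
        for i, p in enumerate(truth.peaks):
            f.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{p.weight!r}\t.\n")
    with open(out / "loops.bedpe", "w") as f:
        f.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tweight\tsupport\n")
        for i, l in enumerate(truth.loops):
            f.write(
                f"{l.chrom}\t{l.start_a}\t{l.end_a}\t{l.chrom}\t{l.start_b}\t{l.end_b}"
                f"\tloop{i}\t{l.weight!r}\t{l.support}\n"
            )
    with open(out / "params.json", "w") as f:
        json.dump({"noise": asdict(truth.noise), "seed": truth.seed}, f, indent=1)
    if pets is not None:
        rows = []
        for i, lp in enumerate(pets):
            a, b = lp.pet.tag_a, lp.pet.tag_b
            rows.append(
                dict(pet_index=i, label=lp.label,
                     loop_id=-1 if lp.loop_id is None else lp.loop_id,
                     dup_of=-1 if lp.dup_of is None else lp.dup_of,
                     chrom_a=a.chrom, start_a=a.start, end_a=a.end,
                     chrom_b=b.chrom, start_b=b.start, end_b=b.end)
            )
        pd.DataFrame(rows).to_csv(out / "pets.tsv", sep="\t", index=False)


def read_truth(out_dir) -> tuple[TruthSet, list[LabeledPET] | None]:
    """Read back files written by :func:`write_truth`."""
    out = Path(out_dir)
    peaks = []
    with open(out / "peaks.bed") as f:
        for line in f:
            c, s, e, _name, w, _strand = line.rstrip("\n").split("\t")
            peaks.append(TruthPeak(c, int(s), int(e), float(w)))
    loops = []
    with open(out / "loops.bedpe") as f:
        for line in f:
            if line.startswith("#"):
                continue
            c1, s1, e1, _c2, s2, e2, _name, w, sup = line.rstrip("\n").split("\t")
            loops.append(TruthLoop(c1, int(s1), int(e1), int(s2), int(e2), float(w), sup))
    with open(out / "params.json") as f:
        meta = json.load(f)
    truth = TruthSet(peaks, loops, NoiseParams(**meta["noise"]), meta["seed"])
    pets = None
    pets_path = out / "pets.tsv"
    if pets_path.exists():
        df = pd.read_csv(pets_path, sep="\t")
        pets = []
        for r in df.itertuples():
            pet = _mk_pet(r.chrom_a, r.start_a, r.end_a - r.start_a,
                          r.chrom_b, r.start_b, r.end_b - r.start_b, r.pet_index)
            pets.append(
                LabeledPET(pet, r.label,
                           loop_id=None if r.loop_id < 0 else int(r.loop_id),
                           dup_of=None if r.dup_of < 0 else int(r.dup_of))
            )
    return truth, pets
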