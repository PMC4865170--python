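"""Study-shaped synthetic datasets with ground truth.

The generator emulates a promoter-trap study of tumor-active Salmonella
promoters: a small positive set whose members carry a strong palindromic
FNR site upstream of a deliberately weak sigma70 basal promoter in a
locally AT-enriched context, a large negative set of transcriptionally
silent genomic fragments, a small independent holdout with further
attenuated basal elements, and a random genomic background cut to the
positive set's length distribution.

Defaults mirror the study conditions: 13 positives, 115 negatives,
12 holdouts, 7682 background fragments; negative/template GC 0.55,
positive-context GC 0.488 (mean A+T 0.512); adenine-run and AT-rich-region
implant probabilities 0.77 each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import catalog
from .features import (
    at_fraction,
    best_pwm_score,
    score_bipartite,
)
from .seqio import PromoterSet, SequenceRecord, make_random_promoter_set

_BASES = np.array(list("ACGT"))


@dataclass
class StudyConfig:
    """Conditions of the emulated study; every scalar is overridable."""

    n_tsp: int = 13
    n_np: int = 115
    n_lowtsp: int = 12
    n_rp: int = 7682
    length_min: int = 150
    length_max: int = 600
    gc_tsp: float = 0.488
    gc_np: float = 0.55
    gc_genome: float = 0.52
    genome_length: int = 200_000
    p_fnr: float = 1.0
    p_basal: float = 1.0
    p_a8: float = 0.77
    p_at_region: float = 0.77
    weak_minus35_mismatches: int = 2
    weak_minus10_mismatches: int = 1
    lowtsp_extra_mismatches: int = 1
    fnr_gap_min: int = 5  # FNR end to -35 start
    fnr_gap_max: int = 60
    spacer_min: int = 15
    spacer_max: int = 21
    colocalization_window: int = 120
    at_region_target: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_tsp, self.n_np, self.n_lowtsp, self.n_rp):
            if n < 1:
                raise ValueError("set sizes must be >= 1")
        for p in (self.p_fnr, self.p_basal, self.p_a8, self.p_at_region):
            if not 0.0 <= p <= 1.0:
                raise ValueError("implant probabilities must be in [0, 1]")
        cassette_max = 14 + self.fnr_gap_max + 12 + self.spacer_max
        if cassette_max > self.colocalization_window:
            # the window caps the realized cassette extent instead
            pass
        if cassette_max > self.length_min:
            raise ValueError("length_min too small for the implant cassette")


@dataclass
class Implant:
    element: str
    start: int
    end: int
    sequence: str
    score: float
    detail: dict = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    """Ground-truth implants per sequence id."""

    implants: dict[str, list[Implant]] = field(default_factory=dict)

    def add(self, seq_id: str, implant: Implant) -> None:
        self.implants.setdefault(seq_id, []).append(implant)

    def elements_in(self, seq_id: str) -> set[str]:
        return {imp.element for imp in self.implants.get(seq_id, [])}


@dataclass
class StudyData:
    tsp: PromoterSet
    np: PromoterSet
    lowtsp: PromoterSet
    rp: PromoterSet
    truth: SyntheticTruth
    config: StudyConfig


def generate_background(length: int, gc: float, seed=None) -> SequenceRecord:
    """i.i.d. bases with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in the open interval (0, 1)")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return SequenceRecord(id=f"bg_{length}", sequence=seq)


def weaken_element(
    consensus: str,
    n_mismatches: int,
    protected_offsets=(),
    seed=None,
) -> str:
    """Introduce exactly n seeded substitutions outside protected offsets."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    free = [i for i in range(len(consensus)) if i not in set(protected_offsets)]
    if n_mismatches > len(free):
        raise ValueError("more mismatches requested than unprotected positions")
    positions = rng.choice(len(free), size=n_mismatches, replace=False)
    out = list(consensus.upper())
    for idx in positions:
        pos = free[int(idx)]
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def _random_core(rng: np.random.Generator, length: int = 4) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _place_cassette(seq: list, length: int, cfg: StudyConfig, rng, extra_mm: int):
    """Implant FNR + weak basal pair; returns the implant descriptions."""
    fnr_site = "TTGAT" + _random_core(rng) + "ATCAA"
    gap = int(rng.integers(cfg.fnr_gap_min, cfg.fnr_gap_max + 1))
    spacer = int(rng.integers(cfg.spacer_min, cfg.spacer_max + 1))
    weak35 = weaken_element(catalog.MINUS35_CONSENSUS,
                            cfg.weak_minus35_mismatches + extra_mm, seed=rng)
    weak10 = weaken_element(catalog.MINUS10_CONSENSUS,
                            cfg.weak_minus10_mismatches + extra_mm, seed=rng)
    cassette_len = 14 + gap + 6 + spacer + 6
    margin = 10  # keep the reported TSS inside the fragment
    start = int(rng.integers(0, length - cassette_len - margin + 1))
    fnr_start = start
    m35_start = start + 14 + gap
    m10_start = m35_start + 6 + spacer
    implants = []
    if rng.random() < cfg.p_fnr:
        seq[fnr_start : fnr_start + 14] = list(fnr_site)
        implants.append(("FNR", fnr_start, fnr_start + 14, fnr_site,
                         {"core": fnr_site[5:9]}))
    if rng.random() < cfg.p_basal:
        seq[m35_start : m35_start + 6] = list(weak35)
        seq[m10_start : m10_start + 6] = list(weak10)
        implants.append(("BasalP", m35_start, m10_start + 6, weak35 + "|" + weak10,
                         {"minus35": weak35, "minus10": weak10, "spacer": spacer}))
    return implants, (fnr_start, m10_start + 6)


def _implant_a8(seq: list, occupied: list, rng) -> tuple | None:
    length = len(seq)
    candidates = [
        s for s in range(0, length - 8 + 1)
        if all(s + 8 <= lo or s >= hi for lo, hi in occupied)
    ]
    if not candidates:
        return None
    s = candidates[int(rng.integers(0, len(candidates)))]
    seq[s : s + 8] = list("AAAAAAAA")
    return ("A8", s, s + 8, "AAAAAAAA", {})


def _enrich_window(seq: list, occupied: list, center: int, cfg: StudyConfig, rng):
    """Raise a 100 nt window's A+T fraction above the AT-region cutoff by
    converting G/C outside implanted elements to A or T (balanced, as in a
    naturally AT-rich genomic context; adenine runs are implanted
    separately so the two signals stay independent)."""
    length = len(seq)
    window = 100
    if length < window:
        return None
    lo = max(0, min(center - window // 2, length - window))
    hi = lo + window
    editable = [
        i for i in range(lo, hi)
        if seq[i] in "GC" and all(i < a or i >= b for a, b in occupied)
    ]
    order = rng.permutation(len(editable))
    at = sum(1 for i in range(lo, hi) if seq[i] in "AT")
    target = int(np.ceil(cfg.at_region_target * window))
    edits = 0
    for idx in order:
        if at >= target:
            break
        i = editable[int(idx)]
        seq[i] = "A" if rng.random() < 0.5 else "T"
        at += 1
        edits += 1
    if at < target:
        return None
    return ("ATregion", lo, hi, "".join(seq[lo:hi]), {"edits": edits})


def _positive_like(
    rec_id: str,
    label: str,
    cfg: StudyConfig,
    rng: np.random.Generator,
    truth: SyntheticTruth,
    extra_mm: int,
) -> SequenceRecord:
    length = int(rng.integers(cfg.length_min, cfg.length_max + 1))
    seq = list(generate_background(length, cfg.gc_tsp, rng).sequence)
    implants, cassette_span = _place_cassette(seq, length, cfg, rng, extra_mm)
    occupied = [(s, e) for _, s, e, _, _ in implants]
    if rng.random() < cfg.p_a8:
        a8 = _implant_a8(seq, occupied, rng)
        if a8 is not None:
            implants.append(a8)
            occupied.append((a8[1], a8[2]))
    if rng.random() < cfg.p_at_region:
        center = (cassette_span[0] + cassette_span[1]) // 2
        atr = _enrich_window(seq, occupied, center, cfg, rng)
        if atr is not None:
            implants.append(atr)
    record = SequenceRecord(id=rec_id, sequence="".join(seq), label=label)
    for element, start, end, implanted, detail in implants:
        score = _detection_score(record.sequence, element, start, end, detail)
        truth.add(rec_id, Implant(element, start, end, implanted, score, detail))
    return record


def _detection_score(sequence: str, element: str, start: int, end: int, detail: dict):
    """Score the implant as the default catalogue detectors will see it."""
    if element == "FNR":
        return best_pwm_score(sequence[start:end], catalog.fnr_matrix(), "forward")
    if element == "BasalP":
        hit = score_bipartite(sequence[start:end], catalog.basal_model())
        return hit.score if hit is not None else float("-inf")
    if element == "A8":
        return 1.0  # adenine fraction of the implanted run
    if element == "ATregion":
        return at_fraction(sequence[start:end])
    raise ValueError(element)


def generate_study(config: StudyConfig | None = None) -> StudyData:
    """Generate the four labeled sets and their ground truth.

    Fully reproducible from the config (including its seed): positives and
    holdouts carry the FNR + weak-basal cassette (holdouts with extra basal
    mismatches), negatives are plain background, and the random set is cut
    from a synthetic genome following the positive length distribution.
    """
    cfg = config or StudyConfig()
    master = np.random.default_rng(cfg.seed)
    child_seeds = master.integers(0, 2**31 - 1, size=5)
    truth = SyntheticTruth()

    rng_tsp = np.random.default_rng(child_seeds[0])
    tsp = PromoterSet(
        "TSP",
        [_positive_like(f"TSP_{i + 1}", "TSP", cfg, rng_tsp, truth, 0)
         for i in range(cfg.n_tsp)],
        label="TSP",
    )
    rng_low = np.random.default_rng(child_seeds[1])
    lowtsp = PromoterSet(
        "lowTSP",
        [_positive_like(f"lowTSP_{i + 1}", "lowTSP", cfg, rng_low, truth,
                        cfg.lowtsp_extra_mismatches)
         for i in range(cfg.n_lowtsp)],
        label="lowTSP",
    )
    rng_np = np.random.default_rng(child_seeds[2])
    np_records = []
    for i in range(cfg.n_np):
        length = int(rng_np.integers(cfg.length_min, cfg.length_max + 1))
        np_records.append(
            SequenceRecord(
                id=f"NP_{i + 1}",
                sequence=generate_background(length, cfg.gc_np, rng_np).sequence,
                label="NP",
            )
        )
    np_set = PromoterSet("NP", np_records, label="NP")

    genome = generate_background(cfg.genome_length, cfg.gc_genome,
                                 np.random.default_rng(child_seeds[3]))
    rp = make_random_promoter_set(genome, tsp, cfg.n_rp, int(child_seeds[4]))
    return StudyData(tsp=tsp, np=np_set, lowtsp=lowtsp, rp=rp, truth=truth,
                     config=cfg)
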