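"""Sequence feature detectors: PWM motifs, the bipartite sigma70 basal
promoter, AT-rich regions and adenine homopolymer repeats.

All motif scores are log-odds in bits against a background base
composition.  ``N`` bases score as background (log-odds contribution 0).
Hits use 0-based half-open coordinates on the forward strand; a
reverse-strand PWM hit is reported in forward coordinates with strand
``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Uniform background used when no set composition is supplied.
UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def encode(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0, C=1, G=2, T=3, N=4."""
    return np.frombuffer(
        sequence.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8,
    ).astype(np.int64)


@dataclass(frozen=True)
class WeightMatrix:
    """Position probability matrix over {A,C,G,T} with log-odds scoring.

    ``probabilities`` has shape (4, width) ordered A, C, G, T; every
    column sums to 1 and all entries are strictly positive (a pseudocount
    is mixed in on construction so zero counts never yield -inf scores).
    """

    feature_id: str
    probabilities: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError("probabilities must have shape (4, width>=1)")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a length-4 distribution")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("matrix columns must sum to 1")
        if np.any(probs <= 0):
            raise ValueError("probabilities must be strictly positive (apply pseudocount)")
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probabilities.argmax(axis=0))

    @classmethod
    def from_counts(
        cls,
        feature_id: str,
        counts,
        background=None,
        pseudocount: float = 0.01,
    ) -> "WeightMatrix":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=0)
        bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background)
        return cls(feature_id, probs, bg, pseudocount)

    @classmethod
    def from_probabilities(
        cls,
        feature_id: str,
        probs,
        background=None,
        pseudocount: float = 0.01,
    ) -> "WeightMatrix":
        probs = np.asarray(probs, dtype=float)
        mixed = (probs + pseudocount) / (probs + pseudocount).sum(axis=0)
        bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background)
        return cls(feature_id, mixed, bg, pseudocount)

    def log_odds(self) -> np.ndarray:
        """(5, width) log2 odds table; row 4 (N) is zero (background)."""
        table = np.zeros((5, self.width))
        table[:4] = np.log2(self.probabilities / self.background[:, None])
        return table

    def max_score(self) -> float:
        return float(self.log_odds()[:4].max(axis=0).sum())

    def with_background(self, background) -> "WeightMatrix":
        return WeightMatrix(self.feature_id, self.probabilities, np.asarray(background),
                            self.pseudocount)


@dataclass(frozen=True)
class FeatureHit:
    """A located, scored feature occurrence (0-based, half-open, stranded)."""

    feature_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"
    score: float = 0.0
    parts: dict | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad hit interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class BipartitePromoterModel:
    """Two hexamer matrices (-35 and -10/TATA box) joined by a flexible spacer.

    The total score of a (-35, -10) placement is the sum of the two
    log-odds scores minus ``spacer_penalty`` bits per nt of deviation of
    the spacer from the 17 nt sigma70 optimum.  The transcription start
    (TSS/Inr) is placed ``tss_offset`` nt downstream of the -10 end.
    """

    minus35: WeightMatrix
    minus10: WeightMatrix
    spacer_min: int = 15
    spacer_max: int = 21
    spacer_optimum: int = 17
    spacer_penalty: float = 0.5
    tss_offset: int = 7

    def __post_init__(self) -> None:
        if self.minus35.width != 6 or self.minus10.width != 6:
            raise ValueError("both promoter elements must be 6 nt wide")
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min must be <= spacer_max")

    @property
    def min_sequence_length(self) -> int:
        return 12 + self.spacer_min


@dataclass
class FeatureDefinition:
    """A named detector: pwm | bipartite | at_region | a_repeat.

    ``parameters`` is kind-specific: ``{"matrix": WeightMatrix}``,
    ``{"model": BipartitePromoterModel}``, ``{"window": int,
    "min_fraction": float}`` or ``{"repeat_len": int, "max_mismatch": int}``.
    """

    feature_id: str
    kind: str
    parameters: dict
    strands_scanned: str = "forward"

    _REQUIRED = {
        "pwm": {"matrix"},
        "bipartite": {"model"},
        "at_region": {"window", "min_fraction"},
        "a_repeat": {"repeat_len", "max_mismatch"},
    }

    def __post_init__(self) -> None:
        if self.kind not in self._REQUIRED:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        missing = self._REQUIRED[self.kind] - set(self.parameters)
        if missing:
            raise ValueError(f"{self.feature_id}: missing parameters {sorted(missing)}")
        if self.strands_scanned not in ("forward", "both"):
            raise ValueError("strands_scanned must be 'forward' or 'both'")


# ---------------------------------------------------------------------------
# composition statistics


def at_fraction(sequence: str) -> float:
    """(A + T count) / length; N counts as neither base."""
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    return (sequence.count("A") + sequence.count("T")) / len(sequence)


def find_at_rich_regions(
    sequence: str,
    seq_id: str = "seq",
    window: int = 100,
    min_fraction: float = 0.6,
    feature_id: str = "ATregion",
) -> list[FeatureHit]:
    """Maximal regions covered by length-``window`` substrings with A+T
    fraction strictly above ``min_fraction``.

    Overlapping qualifying windows are merged; sequences shorter than the
    window yield no hits.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sequence = sequence.upper()
    n = len(sequence)
    if n < window:
        return []
    is_at = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_at = ((is_at == ord("A")) | (is_at == ord("T"))).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(is_at)])
    counts = csum[window:] - csum[:-window]  # AT count of window starting at i
    qualifying = counts / window > min_fraction
    return _merge_windows(qualifying, window, seq_id, feature_id, counts / window)


def find_a_repeats(
    sequence: str,
    seq_id: str = "seq",
    repeat_len: int = 8,
    max_mismatch: int = 1,
    feature_id: str = "A8",
) -> list[FeatureHit]:
    """Maximal runs covered by length-``repeat_len`` windows containing at
    least ``repeat_len - max_mismatch`` adenines.  Forward strand only.
    """
    if repeat_len < 1:
        raise ValueError("repeat_len must be >= 1")
    if not (0 <= max_mismatch < repeat_len):
        raise ValueError("max_mismatch must be in [0, repeat_len)")
    sequence = sequence.upper()
    n = len(sequence)
    if n < repeat_len:
        return []
    is_a = (np.frombuffer(sequence.encode(), dtype=np.uint8) == ord("A")).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(is_a)])
    counts = csum[repeat_len:] - csum[:-repeat_len]
    qualifying = counts >= repeat_len - max_mismatch
    return _merge_windows(qualifying, repeat_len, seq_id, feature_id,
                          counts / repeat_len)


def _merge_windows(qualifying, window, seq_id, feature_id, window_scores):
    """Merge overlapping qualifying fixed-width windows into maximal regions."""
    hits: list[FeatureHit] = []
    idx = np.flatnonzero(qualifying)
    if idx.size == 0:
        return hits
    run_start = int(idx[0])
    prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i > prev + window:  # windows [prev, prev+w) and [i, i+w) disjoint
            hits.append(_region_hit(run_start, prev, window, seq_id, feature_id,
                                    window_scores))
            run_start = i
        prev = i
    hits.append(_region_hit(run_start, prev, window, seq_id, feature_id, window_scores))
    return hits


def _region_hit(first, last, window, seq_id, feature_id, window_scores):
    score = float(window_scores[first : last + 1].max())
    return FeatureHit(feature_id=feature_id, seq_id=seq_id, start=first,
                      end=last + window, strand="+", score=score)


# ---------------------------------------------------------------------------
# PWM scanning


def _window_scores(codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; vectorized over positions."""
    width = lod.shape[1]
    n = codes.size - width + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(width):
        scores += lod[codes[j : j + n], j]
    return scores


def scan_pwm(
    sequence: str,
    matrix: WeightMatrix,
    threshold: float,
    seq_id: str = "seq",
    strands: str = "both",
) -> list[FeatureHit]:
    """All windows scoring >= threshold (log2 odds vs background).

    Reverse-strand hits are reported in forward coordinates with strand
    ``-``.  A matrix wider than the sequence yields an empty list.
    """
    sequence = sequence.upper()
    n = len(sequence)
    w = matrix.width
    if w > n:
        return []
    lod = matrix.log_odds()
    hits = []
    codes = encode(sequence)
    fwd = _window_scores(codes, lod)
    for i in np.flatnonzero(fwd >= threshold):
        hits.append(FeatureHit(matrix.feature_id, seq_id, int(i), int(i) + w,
                               "+", float(fwd[i])))
    if strands == "both":
        rc_codes = encode(reverse_complement(sequence))
        rev = _window_scores(rc_codes, lod)
        for i in np.flatnonzero(rev >= threshold):
            start = n - int(i) - w  # forward coordinates of the rc window
            hits.append(FeatureHit(matrix.feature_id, seq_id, start, start + w,
                                   "-", float(rev[i])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def best_pwm_score(sequence: str, matrix: WeightMatrix, strands: str = "both") -> float:
    """Maximum window log-odds score over the requested strands (-inf if none fits)."""
    sequence = sequence.upper()
    if matrix.width > len(sequence):
        return float("-inf")
    lod = matrix.log_odds()
    best = _window_scores(encode(sequence), lod).max()
    if strands == "both":
        rev = _window_scores(encode(reverse_complement(sequence)), lod)
        best = max(best, rev.max())
    return float(best)


def consensus_to_matrix(
    consensus: str,
    feature_id: str | None = None,
    match_probability: float = 0.91,
    background=None,
) -> WeightMatrix:
    """Build a WeightMatrix from an IUPAC consensus string.

    Matched bases share ``match_probability``; the remainder is spread
    uniformly over the other bases.  ``N`` positions get the background
    distribution (scoring 0 everywhere).
    """
    consensus = consensus.upper()
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    p = min(match_probability, 1.0 - 3e-9)
    cols = []
    for code in consensus:
        allowed = IUPAC.get(code)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {code!r}")
        if code == "N":
            cols.append(bg.copy())
            continue
        col = np.full(4, (1.0 - p) / (4 - len(allowed)) if len(allowed) < 4 else 0.0)
        for b in allowed:
            col[_BASE_INDEX[b]] = p / len(allowed)
        cols.append(col / col.sum())
    probs = np.array(cols).T
    return WeightMatrix(feature_id or consensus, probs, bg, pseudocount=0.0)


# ---------------------------------------------------------------------------
# bipartite basal promoter


def score_bipartite(
    sequence: str,
    model: BipartitePromoterModel,
    seq_id: str = "seq",
) -> FeatureHit | None:
    """Best-scoring (-35, spacer, -10) placement on the forward strand.

    Score = -35 log-odds + -10 log-odds - spacer_penalty * |spacer - optimum|.
    Ties are broken by the smaller -35 start.  Returns ``None`` when the
    sequence is shorter than two hexamers plus the minimum spacer.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < model.min_sequence_length:
        return None
    codes = encode(sequence)
    s35 = _window_scores(codes, model.minus35.log_odds())
    s10 = _window_scores(codes, model.minus10.log_odds())
    best_total = -np.inf
    best = None
    for spacer in range(model.spacer_min, model.spacer_max + 1):
        offset = 6 + spacer  # -10 start relative to -35 start
        m = s35.size - offset
        if m <= 0:
            continue
        penalty = model.spacer_penalty * abs(spacer - model.spacer_optimum)
        totals = s35[:m] + s10[offset : offset + m] - penalty
        i = int(np.argmax(totals))
        if totals[i] > best_total or (
            totals[i] == best_total and best is not None and i < best[0]
        ):
            best_total = float(totals[i])
            best = (i, spacer)
    if best is None:
        return None
    i, spacer = best
    m10_start = i + 6 + spacer
    tss = m10_start + 6 + model.tss_offset - 1  # position of the reported start
    parts = {
        "minus35": (i, i + 6),
        "spacer": (i + 6, m10_start),
        "minus10": (m10_start, m10_start + 6),
    }
    end = m10_start + 6
    if tss < n:
        parts["tss"] = (tss, tss + 1)
        end = tss + 1
    return FeatureHit(
        feature_id="BasalP", seq_id=seq_id, start=i, end=end,
        strand="+", score=best_total, parts=parts,
    )


def scan_bipartite(
    sequence: str,
    model: BipartitePromoterModel,
    threshold: float,
    seq_id: str = "seq",
) -> list[FeatureHit]:
    """All non-overlapping (-35, spacer, -10) placements scoring >= threshold.

    Placements are selected greedily best-score-first; two placements
    overlap when their [-35 start, -10 end) extents intersect.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < model.min_sequence_length:
        return []
    codes = encode(sequence)
    s35 = _window_scores(codes, model.minus35.log_odds())
    s10 = _window_scores(codes, model.minus10.log_odds())
    candidates = []
    for spacer in range(model.spacer_min, model.spacer_max + 1):
        offset = 6 + spacer
        m = s35.size - offset
        if m <= 0:
            continue
        penalty = model.spacer_penalty * abs(spacer - model.spacer_optimum)
        totals = s35[:m] + s10[offset : offset + m] - penalty
        for i in np.flatnonzero(totals >= threshold):
            candidates.append((float(totals[i]), int(i), spacer))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    taken: list[tuple[int, int]] = []
    hits = []
    for score, i, spacer in candidates:
        extent = (i, i + 12 + spacer)
        if any(extent[0] < e and s < extent[1] for s, e in taken):
            continue
        taken.append(extent)
        m10_start = i + 6 + spacer
        tss = m10_start + 6 + model.tss_offset - 1
        parts = {
            "minus35": (i, i + 6),
            "spacer": (i + 6, m10_start),
            "minus10": (m10_start, m10_start + 6),
        }
        end = m10_start + 6
        if tss < n:
            parts["tss"] = (tss, tss + 1)
            end = tss + 1
        hits.append(FeatureHit("BasalP", seq_id, i, end, "+", score, parts))
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# unified per-sequence scoring and hit detection for any FeatureDefinition


def feature_score(record_or_seq, feature: FeatureDefinition) -> float:
    """Best per-sequence score of a feature: the quantity thresholds act on.

    pwm/bipartite: maximal log-odds; at_region: maximal window A+T
    fraction (-inf if shorter than the window); a_repeat: maximal window
    adenine fraction.
    """
    seq = getattr(record_or_seq, "sequence", record_or_seq).upper()
    if feature.kind == "pwm":
        return best_pwm_score(seq, feature.parameters["matrix"], feature.strands_scanned)
    if feature.kind == "bipartite":
        hit = score_bipartite(seq, feature.parameters["model"])
        return float("-inf") if hit is None else hit.score
    if feature.kind == "at_region":
        window = feature.parameters["window"]
        if len(seq) < window:
            return float("-inf")
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_at = ((arr == ord("A")) | (arr == ord("T"))).astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(is_at)])
        return float((csum[window:] - csum[:-window]).max() / window)
    if feature.kind == "a_repeat":
        rlen = feature.parameters["repeat_len"]
        if len(seq) < rlen:
            return float("-inf")
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_a = (arr == ord("A")).astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(is_a)])
        return float((csum[rlen:] - csum[:-rlen]).max() / rlen)
    raise ValueError(feature.kind)


def find_hits(
    record_or_seq,
    feature: FeatureDefinition,
    threshold: float | None = None,
    seq_id: str | None = None,
) -> list[FeatureHit]:
    """All hits of a feature on one sequence.

    For pwm/bipartite a threshold is required (bipartite returns the best
    placement if it clears the threshold); region features use their own
    window/min_fraction or repeat parameters and ignore the threshold
    unless one is given, in which case it overrides ``min_fraction`` /
    the adenine-fraction cutoff.
    """
    seq = getattr(record_or_seq, "sequence", record_or_seq).upper()
    sid = seq_id or getattr(record_or_seq, "id", "seq")
    if feature.kind == "pwm":
        if threshold is None:
            raise ValueError("pwm features require a threshold")
        hits = scan_pwm(seq, feature.parameters["matrix"], threshold, sid,
                        feature.strands_scanned)
        return [
            FeatureHit(feature.feature_id, h.seq_id, h.start, h.end, h.strand, h.score)
            for h in hits
        ]
    if feature.kind == "bipartite":
        if threshold is None:
            raise ValueError("bipartite features require a threshold")
        hits = scan_bipartite(seq, feature.parameters["model"], threshold, sid)
        return [FeatureHit(feature.feature_id, h.seq_id, h.start, h.end,
                           h.strand, h.score, h.parts) for h in hits]
    if feature.kind == "at_region":
        min_fraction = feature.parameters["min_fraction"] if threshold is None else threshold
        return find_at_rich_regions(seq, sid, feature.parameters["window"],
                                    min_fraction, feature.feature_id)
    if feature.kind == "a_repeat":
        rlen = feature.parameters["repeat_len"]
        if threshold is None:
            max_mm = feature.parameters["max_mismatch"]
        else:
            # threshold is an adenine fraction; convert to a mismatch budget
            max_mm = min(rlen - 1, int(np.floor(rlen * (1 - threshold) + 1e-9)))
        return find_a_repeats(seq, sid, rlen, max_mm, feature.feature_id)
    raise ValueError(feature.kind)
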