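"""Promoter engineering: fragment splitting, motif knockouts, spacer
randomization, FNR-site symmetrization and composition of artificial
promoters by implanting elements into a neutral template.

Every operation returns a :class:`DesignPlan` whose edits, applied in
order to the template, reproduce the stored product exactly.  Products are
verified by re-scanning with the same detectors used for discovery: a
knockout must abolish the hit at its locus, an implant must be
re-detected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .features import (
    FeatureDefinition,
    FeatureHit,
    at_fraction,
    find_hits,
    reverse_complement,
)
from .seqio import SequenceRecord

PROVENANCE = ("critical_knockout", "noncritical_randomize", "spacer_randomize",
              "implant", "melting")


@dataclass(frozen=True)
class DesignEdit:
    kind: str  # substitute | delete | implant | at_enrich
    position: int
    original: str
    replacement: str
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCE:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.position < 0:
            raise ValueError("edit position must be >= 0")

    @property
    def span(self) -> tuple[int, int]:
        return (self.position, self.position + len(self.original))


@dataclass
class ExpectedFeature:
    """A feature the product must (or must not) contain near a locus."""

    feature: FeatureDefinition
    threshold: float
    required: bool = True
    locus: tuple[int, int] | None = None  # restrict the check to this span


@dataclass
class DesignPlan:
    template: SequenceRecord
    edits: list[DesignEdit]
    product: SequenceRecord
    expected_features: list[ExpectedFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        spans = sorted(e.span for e in self.edits)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("edits within one plan must not overlap")
        if apply_edits(self.template.sequence, self.edits) != self.product.sequence:
            raise ValueError("edits do not reproduce the stored product")

    def to_json(self) -> str:
        return json.dumps(
            {
                "template_id": self.template.id,
                "template_sequence": self.template.sequence,
                "product_id": self.product.id,
                "product_sequence": self.product.sequence,
                "edits": [
                    {"kind": e.kind, "position": e.position, "original": e.original,
                     "replacement": e.replacement, "provenance": e.provenance}
                    for e in self.edits
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DesignPlan":
        data = json.loads(text)
        template = SequenceRecord(data["template_id"], data["template_sequence"],
                                  "designed")
        product = SequenceRecord(data["product_id"], data["product_sequence"],
                                 "designed")
        edits = [DesignEdit(**e) for e in data["edits"]]
        return cls(template, edits, product)


def apply_edits(sequence: str, edits: list[DesignEdit]) -> str:
    """Apply non-overlapping edits right-to-left so positions stay valid."""
    out = sequence
    for e in sorted(edits, key=lambda e: -e.position):
        s, t = e.span
        if out[s:t] != e.original:
            raise ValueError(
                f"edit at {s}: template has {out[s:t]!r}, expected {e.original!r}"
            )
        out = out[:s] + e.replacement + out[t:]
    return out


def _substitutions(template: str, product: str, positions, provenance: str):
    return [
        DesignEdit("substitute", p, template[p], product[p], provenance)
        for p in sorted(positions)
        if template[p] != product[p]
    ]


# ---------------------------------------------------------------------------
# fragment splitting


def split_promoter(
    record: SequenceRecord,
    hits: list[FeatureHit],
    len_range: tuple[int, int] = (50, 100),
) -> list[SequenceRecord]:
    """Partition a promoter into testable fragments of 50-100 nt.

    Cut points avoid bisecting any hit where possible; fragment ids are
    the parent id plus an underscore and a consecutive number.  A terminal
    fragment may fall below the minimum length and a fragment spanning a
    hit longer than the maximum may exceed it; both are tolerated.
    """
    lo, hi = len_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid length range")
    if record.length <= lo:
        raise ValueError("record not longer than the minimum fragment length")
    n = record.length
    forbidden = np.zeros(n + 1, dtype=bool)
    for h in hits:
        forbidden[h.start + 1 : h.end] = True  # interior points of the hit
    cuts = [0]
    pos = 0
    while n - pos > hi:
        window = [c for c in range(pos + lo, min(pos + hi, n - 1) + 1) if not forbidden[c]]
        if window:
            # furthest allowed cut keeps fragments few and near the maximum
            cut = window[-1]
        else:
            # a hit spans the whole window: cut at its end (fragment oversize)
            cut = pos + hi
            while cut < n and forbidden[cut]:
                cut += 1
        cuts.append(cut)
        pos = cut
    cuts.append(n)
    fragments = []
    for i, (s, t) in enumerate(zip(cuts, cuts[1:]), start=1):
        fragments.append(
            SequenceRecord(id=f"{record.id}_{i}", sequence=record.sequence[s:t],
                           label="designed")
        )
    return fragments


# ---------------------------------------------------------------------------
# knockouts and randomization


def knockout(
    record: SequenceRecord,
    hit: FeatureHit,
    critical_offsets: list[int],
    seed=None,
    feature: FeatureDefinition | None = None,
    threshold: float | None = None,
    replacement_alphabet: str = "ACGT",
) -> DesignPlan:
    """Substitute a hit's critical positions with seeded random other bases.

    For basal-promoter (TATA box) knockouts pass
    ``replacement_alphabet="GC"`` so only G and C are introduced.  When the
    feature and its threshold are given, the product is expected to show
    no hit of that feature overlapping the original locus.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    width = hit.end - hit.start
    for off in critical_offsets:
        if not 0 <= off < width:
            raise ValueError(f"critical offset {off} outside hit of width {width}")
    seq = list(record.sequence)
    edits = []
    for off in sorted(critical_offsets):
        pos = hit.start + off
        choices = [b for b in replacement_alphabet if b != seq[pos]]
        if not choices:
            raise ValueError(f"no replacement base available at position {pos}")
        new = choices[int(rng.integers(0, len(choices)))]
        edits.append(DesignEdit("substitute", pos, seq[pos], new,
                                "critical_knockout"))
        seq[pos] = new
    product = SequenceRecord(id=f"{record.id}_ko_{hit.feature_id}",
                             sequence="".join(seq), label="designed")
    expected = []
    if feature is not None and threshold is not None:
        expected.append(ExpectedFeature(feature, threshold, required=False,
                                        locus=(hit.start, hit.end)))
    return DesignPlan(record, edits, product, expected)


def randomize_positions(
    record: SequenceRecord,
    positions: list[int],
    seed=None,
    preserve: list[ExpectedFeature] | None = None,
    max_attempts: int = 20,
) -> DesignPlan:
    """Seeded random substitutions at the listed positions.

    Every preserved feature must still be detected at its locus afterwards;
    failing draws are retried with fresh randomness up to ``max_attempts``
    times before the plan is rejected.
    """
    from .catalog import CRITICAL_OFFSETS

    preserve = preserve or []
    pos_set = set(positions)
    for exp in preserve:
        if exp.locus is None:
            continue
        critical = {
            exp.locus[0] + off
            for off in CRITICAL_OFFSETS.get(exp.feature.feature_id, [])
        }
        clash = pos_set & critical
        if clash:
            raise ValueError(
                f"positions {sorted(clash)} are critical for preserved feature "
                f"{exp.feature.feature_id}"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _attempt in range(max_attempts):
        seq = list(record.sequence)
        edits = []
        for pos in sorted(pos_set):
            alternatives = [b for b in "ACGT" if b != seq[pos]]
            new = alternatives[int(rng.integers(0, 3))]
            edits.append(DesignEdit("substitute", pos, seq[pos], new,
                                    "noncritical_randomize"))
            seq[pos] = new
        product = SequenceRecord(id=f"{record.id}_rand", sequence="".join(seq),
                                 label="designed")
        plan = DesignPlan(record, edits, product, preserve)
        if all(_expectation_met(product, exp) for exp in preserve):
            return plan
    raise ValueError(
        f"could not randomize {len(pos_set)} positions in {max_attempts} attempts "
        "without destroying a preserved feature"
    )


def symmetrize_fnr(record: SequenceRecord, hit: FeatureHit) -> DesignPlan:
    """Make an FNR site a perfect palindrome around its 4 nt core.

    The site structure is 5 + 4 + 5 nt; the second half-site is replaced
    by the reverse complement of the first, which can only raise the score
    of a palindromic-consensus matrix.
    """
    if hit.end - hit.start != 14:
        raise ValueError("FNR site must be 14 nt (5 + 4 + 5)")
    site = record.sequence[hit.start : hit.end]
    first_half = site[:5]
    new_second = reverse_complement(first_half)
    positions = [hit.start + 9 + i for i in range(5) if site[9 + i] != new_second[i]]
    seq = list(record.sequence)
    for i in range(5):
        seq[hit.start + 9 + i] = new_second[i]
    product = SequenceRecord(id=f"{record.id}_symFNR", sequence="".join(seq),
                             label="designed")
    edits = _substitutions(record.sequence, product.sequence, positions,
                           "noncritical_randomize")
    return DesignPlan(record, edits, product)


# ---------------------------------------------------------------------------
# composition


def compose_promoter(
    template: SequenceRecord,
    parts: list[tuple[str, int]],
    at_enrich: tuple[int, int, float] | None = None,
    seed=None,
    expected_features: list[ExpectedFeature] | None = None,
    product_id: str | None = None,
) -> DesignPlan:
    """Implant element strings into a template and optionally AT-enrich a
    window around the prospective transcription start.

    ``parts`` are (element string, offset) pairs that must fit without
    overlapping.  ``at_enrich`` = (center, halfwidth, target_fraction)
    converts seeded G/C positions outside the implants to A (p=0.75) or T
    until the window's A+T fraction reaches the target; this mimics
    lowering the melting temperature around the start site.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spans = []
    for elem, off in parts:
        if off < 0 or off + len(elem) > template.length:
            raise ValueError(f"part at offset {off} does not fit the template")
        spans.append((off, off + len(elem)))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("implanted parts overlap")
    seq = list(template.sequence)
    edits: list[DesignEdit] = []
    for elem, off in parts:
        elem = elem.upper()
        original = template.sequence[off : off + len(elem)]
        if original != elem:
            edits.append(DesignEdit("implant", off, original, elem, "implant"))
        seq[off : off + len(elem)] = list(elem)
    occupied = [(s, e) for s, e in spans]
    if at_enrich is not None:
        center, halfwidth, target = at_enrich
        lo = max(0, center - halfwidth)
        hi = min(template.length, center + halfwidth)
        window = range(lo, hi)
        editable = [
            i for i in window
            if seq[i] in "GC" and all(i < a or i >= b for a, b in occupied)
        ]
        order = rng.permutation(len(editable))
        current = sum(1 for i in window if seq[i] in "AT")
        needed = int(np.ceil(target * (hi - lo)))
        for idx in order:
            if current >= needed:
                break
            i = editable[int(idx)]
            new = "A" if rng.random() < 0.75 else "T"
            edits.append(DesignEdit("at_enrich", i, seq[i], new, "melting"))
            seq[i] = new
            current += 1
        if current < needed:
            raise ValueError(
                f"cannot reach A+T fraction {target} in [{lo},{hi}) without "
                "editing implanted parts"
            )
    product = SequenceRecord(id=product_id or f"{template.id}_composed",
                             sequence="".join(seq), label="designed")
    return DesignPlan(template, edits, product, expected_features or [])


# ---------------------------------------------------------------------------
# verification


def _expectation_met(product: SequenceRecord, exp: ExpectedFeature) -> bool:
    hits = find_hits(product, exp.feature, exp.threshold)
    if exp.locus is not None:
        lo, hi = exp.locus
        hits = [h for h in hits if h.start < hi and lo < h.end]
    return bool(hits) == exp.required


def verify_design(plan: DesignPlan, tss: int | None = None) -> dict:
    """Re-scan the product against every expectation; report pass/fail.

    Also reports a melting proxy: the A+T fraction of a +/-10 nt window
    around the given transcription start, when one is supplied.
    """
    checks = []
    for exp in plan.expected_features:
        hits = find_hits(plan.product, exp.feature, exp.threshold)
        if exp.locus is not None:
            lo, hi = exp.locus
            hits = [h for h in hits if h.start < hi and lo < h.end]
        ok = bool(hits) == exp.required
        checks.append(
            {
                "feature_id": exp.feature.feature_id,
                "required": exp.required,
                "found": [(h.start, h.end, round(h.score, 4)) for h in hits],
                "passed": ok,
            }
        )
    report = {
        "product_id": plan.product.id,
        "n_edits": len(plan.edits),
        "checks": checks,
        "passed": all(c["passed"] for c in checks),
    }
    if tss is not None:
        lo = max(0, tss - 10)
        hi = min(plan.product.length, tss + 11)
        report["tss_melting_at_fraction"] = at_fraction(plan.product.sequence[lo:hi])
    return report
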