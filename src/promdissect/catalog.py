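"""Built-in feature catalogue: the elements dissected out of tumor-specific
Salmonella promoters, with the critical positions used for knockouts.

Element strings follow the published promoter architecture: the FNR
anaerobic activator binds a palindromic TTGAT-N4-ATCAA site; the sigma70
basal promoter pairs a -35 hexamer with a -10 hexamer (TATA box) across a
15-21 nt spacer.  The -35 consensus is kept as the printed study string
``TTGTCA``; the canonical ``TTGACA`` variant is available via
``canonical_minus35=True``.
"""

from __future__ import annotations

from .features import (
    BipartitePromoterModel,
    FeatureDefinition,
    consensus_to_matrix,
)

FNR_CONSENSUS = "TTGATNNNNATCAA"
MINUS35_CONSENSUS = "TTGTCA"
MINUS35_CANONICAL = "TTGACA"
MINUS10_CONSENSUS = "TATAAT"
INR_MOTIF = "AATAAAC"

#: Critical positions (offsets within the motif) whose substitution is
#: expected to abolish binding.  FNR: the two 5 nt half-sites; basal
#: promoter: all six -10 positions.  The catalogue is data, not code —
#: callers may override per feature.
CRITICAL_OFFSETS: dict[str, list[int]] = {
    "FNR": [0, 1, 2, 3, 4, 9, 10, 11, 12, 13],
    "BasalP": [0, 1, 2, 3, 4, 5],
}


def fnr_matrix(match_probability: float = 0.91, background=None):
    return consensus_to_matrix(FNR_CONSENSUS, "FNR", match_probability, background)


def basal_model(
    match_probability: float = 0.91,
    background=None,
    canonical_minus35: bool = False,
) -> BipartitePromoterModel:
    m35 = MINUS35_CANONICAL if canonical_minus35 else MINUS35_CONSENSUS
    return BipartitePromoterModel(
        minus35=consensus_to_matrix(m35, "minus35", match_probability, background),
        minus10=consensus_to_matrix(MINUS10_CONSENSUS, "minus10", match_probability,
                                    background),
    )


def default_catalogue(
    match_probability: float = 0.91,
    background=None,
    canonical_minus35: bool = False,
) -> list[FeatureDefinition]:
    """FNR site, bipartite basal promoter, AT-rich region and A8 repeat."""
    return [
        FeatureDefinition("FNR", "pwm",
                          {"matrix": fnr_matrix(match_probability, background)},
                          strands_scanned="both"),
        FeatureDefinition("BasalP", "bipartite",
                          {"model": basal_model(match_probability, background,
                                                canonical_minus35)},
                          strands_scanned="forward"),
        FeatureDefinition("ATregion", "at_region",
                          {"window": 100, "min_fraction": 0.6},
                          strands_scanned="forward"),
        FeatureDefinition("A8", "a_repeat",
                          {"repeat_len": 8, "max_mismatch": 1},
                          strands_scanned="forward"),
    ]
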