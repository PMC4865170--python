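"""Genetic-algorithm discovery of co-localized feature combinations
(regulatory modules) that discriminate the positive promoter set from the
negative set.

A module is a set of 2-5 heterogeneous features plus a span window; a
sequence supports the module iff one hit of every member fits inside a
window of ``max_span`` nt (order-free).  Fitness rewards positive-set
support, penalizes negative-set support, and adds a small compactness
bonus for modules realized in tight windows.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .discrimination import binomial_pvalue
from .features import FeatureHit
from .seqio import PromoterSet

SPAN_MIN = 50
SPAN_MAX = 500


@dataclass
class MotifModule:
    member_features: frozenset[str]
    max_span: int
    support_tsp: float = 0.0
    support_np: float = 0.0
    fitness: float = 0.0
    p_value: float | None = None
    support_rp: float | None = None

    def __post_init__(self) -> None:
        if len(self.member_features) < 2:
            raise ValueError("a module needs at least 2 member features")

    @property
    def members_label(self) -> str:
        return "+".join(sorted(self.member_features))


@dataclass
class GAParams:
    population: int = 200
    generations: int = 100
    tournament_size: int = 3
    mutation_rate: float = 0.2
    crossover_rate: float = 0.7
    elitism: int = 2
    max_members: int = 5
    top_k: int = 10
    compactness_weight: float = 0.1
    stall_generations: int = 20  # early stop after this many stagnant generations


def _hits_on_sequence(
    hits_by_feature: dict[str, list[FeatureHit]], seq_id: str, members
) -> dict[str, list[tuple[int, int]]]:
    per_member = {}
    for m in members:
        per_member[m] = [
            (h.start, h.end) for h in hits_by_feature[m] if h.seq_id == seq_id
        ]
    return per_member


def _min_span_on_sequence(per_member: dict[str, list[tuple[int, int]]]) -> int | None:
    """Smallest window extent containing one hit per member, or None.

    Anchoring the window at each hit start is exhaustive: any feasible
    combination fits in the window starting at its leftmost member.
    """
    if any(not v for v in per_member.values()):
        return None
    anchors = sorted({s for ivs in per_member.values() for s, _ in ivs})
    best = None
    for a in anchors:
        worst_end = a
        ok = True
        for ivs in per_member.values():
            ends = [e for s, e in ivs if s >= a]
            if not ends:
                ok = False
                break
            worst_end = max(worst_end, min(ends))
        if ok:
            extent = worst_end - a
            if best is None or extent < best:
                best = extent
    return best


def module_support(
    module: MotifModule,
    hits_by_feature: dict[str, list[FeatureHit]],
    pset: PromoterSet,
) -> float:
    """Fraction of sequences where all members co-occur within max_span."""
    missing = module.member_features - set(hits_by_feature)
    if missing:
        raise ValueError(f"no hits supplied for member features {sorted(missing)}")
    supported = 0
    for rec in pset:
        per_member = _hits_on_sequence(hits_by_feature, rec.id, module.member_features)
        span = _min_span_on_sequence(per_member)
        if span is not None and span <= module.max_span:
            supported += 1
    return supported / len(pset)


def _evaluate(
    members: frozenset,
    span: int,
    hits_by_feature,
    tsp: PromoterSet,
    np_set: PromoterSet,
    params: GAParams,
    eps: float,
    cache: dict,
) -> tuple[float, float, float]:
    key = (members, span)
    if key in cache:
        return cache[key]
    sup_t = 0
    spans = []
    for rec in tsp:
        per_member = _hits_on_sequence(hits_by_feature, rec.id, members)
        s = _min_span_on_sequence(per_member)
        if s is not None and s <= span:
            sup_t += 1
            spans.append(s)
    sup_n = 0
    for rec in np_set:
        per_member = _hits_on_sequence(hits_by_feature, rec.id, members)
        s = _min_span_on_sequence(per_member)
        if s is not None and s <= span:
            sup_n += 1
    support_tsp = sup_t / len(tsp)
    support_np = sup_n / len(np_set)
    fitness = support_tsp / (support_np + eps)
    if spans:
        mean_span = sum(spans) / len(spans)
        fitness += params.compactness_weight * (1.0 - mean_span / max(span, 1))
    cache[key] = (fitness, support_tsp, support_np)
    return cache[key]


def _random_genotype(features: list[str], rng: random.Random, params: GAParams):
    k = rng.randint(2, min(params.max_members, len(features)))
    members = frozenset(rng.sample(features, k))
    span = rng.randint(SPAN_MIN, SPAN_MAX)
    return members, span


def _mutate(members, span, features, rng, params):
    choice = rng.random()
    mset = set(members)
    if choice < 1 / 3 and len(mset) < min(params.max_members, len(features)):
        pool = [f for f in features if f not in mset]
        if pool:
            mset.add(rng.choice(pool))
    elif choice < 2 / 3 and len(mset) > 2:
        mset.remove(rng.choice(sorted(mset)))
    else:
        pool = [f for f in features if f not in mset]
        if pool and mset:
            mset.remove(rng.choice(sorted(mset)))
            mset.add(rng.choice(pool))
    span = max(SPAN_MIN, min(SPAN_MAX, span + rng.randint(-50, 50)))
    if len(mset) < 2:
        mset = set(members)
    return frozenset(mset), span


def _crossover(g1, g2, features, rng):
    """Single-point crossover on the membership bitvector over the catalogue."""
    point = rng.randint(1, len(features) - 1)
    left, right = set(), set()
    for i, f in enumerate(features):
        src_l = g1[0] if i < point else g2[0]
        src_r = g2[0] if i < point else g1[0]
        if f in src_l:
            left.add(f)
        if f in src_r:
            right.add(f)
    span = rng.choice([g1[1], g2[1]])
    out = []
    for child in (left, right):
        if len(child) >= 2:
            out.append((frozenset(child), span))
    return out


def ga_search(
    hits_by_feature: dict[str, list[FeatureHit]],
    tsp: PromoterSet,
    np_set: PromoterSet,
    params: GAParams | None = None,
    seed: int = 0,
    rp: PromoterSet | None = None,
    rp_hits_by_feature: dict[str, list[FeatureHit]] | None = None,
) -> list[MotifModule]:
    """Evolve feature combinations; return the top-k distinct modules.

    Deterministic given ``seed``.  When a background set and its hits are
    supplied, each returned module carries a binomial enrichment p-value
    of its positive-set count against the background support frequency.
    """
    params = params or GAParams()
    features = sorted(f for f, hits in hits_by_feature.items() if hits)
    if len(features) < 2:
        raise ValueError("need hits for at least 2 features")
    eps = 0.5 / len(np_set)
    rng = random.Random(seed)
    cache: dict = {}

    def fit(g):
        return _evaluate(g[0], g[1], hits_by_feature, tsp, np_set, params, eps, cache)[0]

    population = [_random_genotype(features, rng, params) for _ in range(params.population)]
    best_fit = max((fit(g) for g in population), default=0.0)
    stall = 0
    for _gen in range(params.generations):
        scored = sorted(population, key=fit, reverse=True)
        next_pop = scored[: params.elitism]
        while len(next_pop) < params.population:
            def pick():
                contenders = [rng.choice(population) for _ in range(params.tournament_size)]
                return max(contenders, key=fit)

            p1, p2 = pick(), pick()
            if rng.random() < params.crossover_rate:
                children = _crossover(p1, p2, features, rng) or [p1, p2]
            else:
                children = [p1, p2]
            for child in children:
                if rng.random() < params.mutation_rate:
                    child = _mutate(child[0], child[1], features, rng, params)
                next_pop.append(child)
                if len(next_pop) >= params.population:
                    break
        population = next_pop
        gen_best = max(fit(g) for g in population)
        if gen_best > best_fit + 1e-12:
            best_fit = gen_best
            stall = 0
        else:
            stall += 1
            if stall >= params.stall_generations:
                break

    # dedupe by member set, keep best-fitness span
    by_members: dict[frozenset, tuple] = {}
    for g in population:
        f = fit(g)
        if g[0] not in by_members or f > fit(by_members[g[0]]):
            by_members[g[0]] = g
    ranked = sorted(by_members.values(), key=fit, reverse=True)[: params.top_k]
    out = []
    for members, span in ranked:
        fitness, sup_t, sup_n = _evaluate(
            members, span, hits_by_feature, tsp, np_set, params, eps, cache
        )
        mod = MotifModule(members, span, sup_t, sup_n, fitness)
        if rp is not None and rp_hits_by_feature is not None:
            sup_rp_count = 0
            for rec in rp:
                per_member = _hits_on_sequence(rp_hits_by_feature, rec.id, members)
                s = _min_span_on_sequence(per_member)
                if s is not None and s <= span:
                    sup_rp_count += 1
            mod.support_rp = sup_rp_count / len(rp)
            k = round(sup_t * len(tsp))
            mod.p_value = binomial_pvalue(k, len(tsp), mod.support_rp)
        out.append(mod)
    if out and out[0].fitness <= 1.0 / (1.0 + eps) + 1e-9 and out[0].support_tsp == 0:
        import warnings

        warnings.warn("no feature combination co-occurs in any positive sequence")
    return out


def modules_to_rows(modules: list[MotifModule]) -> list[dict]:
    return [
        {
            "members": m.members_label,
            "max_span": m.max_span,
            "support_tsp": m.support_tsp,
            "support_np": m.support_np,
            "fitness": m.fitness,
            "p_value": m.p_value,
        }
        for m in modules
    ]
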