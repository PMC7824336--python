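"""Campaign execution, quartile aggregation and the algorithm-ranking model.

The model-building pipeline: search every campaign pattern with every
selected algorithm on the domain text, record the character-comparison
(CC) count per (pattern, algorithm), place each algorithm in a quartile
of the pattern's CC spread, group patterns by entropy class, and report
per (class, algorithm) the share of patterns falling in each quartile.
Ranking within a class orders algorithms by first-quartile share (the
fraction of patterns for which the algorithm was among the cheapest),
with deeper quartiles as tie-breaks.  Prediction for an unseen pattern
is then: entropy -> rounded entropy -> (nearest) class -> that class's
ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .entropy_stats import (
    ClassScheme,
    assign_class,
    build_class_scheme,
    round_entropy,
    shannon_entropy,
)
from .matchers import ALGORITHM_IDS, match

__all__ = [
    "CampaignRecord",
    "QuartileShares",
    "RankingModel",
    "run_campaign",
    "assign_quartiles",
    "aggregate_shares",
    "rank_algorithms",
    "build_model",
    "predict",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CampaignRecord:
    """One algorithm's search result on one campaign pattern."""

    pattern: str
    algo: str
    m: int
    comp: int
    patt_ent: float
    patt_ent_round: float
    patt_ent_class: int


def run_campaign(
    text: str,
    patterns: Sequence[str],
    algorithms: Sequence[str] = ALGORITHM_IDS,
    scheme: Optional[ClassScheme] = None,
) -> List[CampaignRecord]:
    """Search every pattern with every algorithm; one record per pair.

    Entropy fields are computed once per pattern.  If no ``scheme`` is
    given, one is built from the campaign's own rounded entropies (the
    normal model-building flow); passing a scheme pins class assignment
    to an existing model, which is what validation campaigns need.
    Patterns longer than the text are recorded with zero comparisons and
    no occurrences rather than rejected.
    """
    if not patterns:
        raise ValueError("patterns must be nonempty")
    if not algorithms:
        raise ValueError("algorithms must be nonempty")
    ents = {p: shannon_entropy(p) for p in set(patterns)}
    rounded = {p: round_entropy(h) for p, h in ents.items()}
    if scheme is None:
        scheme = build_class_scheme(list(rounded.values()))
    records: List[CampaignRecord] = []
    for p in patterns:
        cls = assign_class(rounded[p], scheme)
        for a in algorithms:
            out = match(a, text, p)
            records.append(
                CampaignRecord(
                    pattern=p,
                    algo=a,
                    m=len(p),
                    comp=out.comparisons,
                    patt_ent=ents[p],
                    patt_ent_round=rounded[p],
                    patt_ent_class=cls,
                )
            )
    return records


def _median(sorted_vals: Sequence[float]) -> float:
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return sorted_vals[mid]
    return (sorted_vals[mid - 1] + sorted_vals[mid]) / 2.0


def assign_quartiles(cc_by_algorithm: Mapping[str, float]) -> Dict[str, int]:
    """Place each algorithm in a quartile (1..4) of the pattern's CC spread.

    Thresholds Q1/Q2/Q3 are the medians of the lower half, the whole set
    and the upper half of the CC values (halves exclude the overall median
    when the count is odd).  An algorithm gets quartile 1 if its CC is
    <= Q1, quartile 2 if <= Q2, and so on; ties therefore share the lower
    quartile, and several algorithms can occupy quartile 1 at once.
    """
    if not cc_by_algorithm:
        raise ValueError("need at least one algorithm")
    vals = sorted(cc_by_algorithm.values())
    n = len(vals)
    q2 = _median(vals)
    lower = vals[: n // 2]
    upper = vals[(n + 1) // 2 :]
    q1 = _median(lower) if lower else q2
    q3 = _median(upper) if upper else q2
    out: Dict[str, int] = {}
    for algo, cc in cc_by_algorithm.items():
        if cc <= q1:
            out[algo] = 1
        elif cc <= q2:
            out[algo] = 2
        elif cc <= q3:
            out[algo] = 3
        else:
            out[algo] = 4
    return out


@dataclass(frozen=True)
class QuartileShares:
    """Per (entropy class, algorithm): fraction of patterns per quartile.

    ``shares[class][algo]`` is a (q1, q2, q3, q4) tuple summing to 1 for
    every algorithm of a nonempty class; empty classes carry all-zero
    shares.  ``class_patterns[class]`` counts the patterns in each class.
    """

    algorithms: Tuple[str, ...]
    class_count: int
    shares: Dict[int, Dict[str, Tuple[float, float, float, float]]]
    class_patterns: Dict[int, int]


def aggregate_shares(
    records: Sequence[CampaignRecord],
    class_count: Optional[int] = None,
    algorithms: Optional[Sequence[str]] = None,
) -> QuartileShares:
    """Aggregate campaign records into per-class quartile shares."""
    if not records:
        raise ValueError("records must be nonempty")
    if algorithms is None:
        algorithms = sorted({r.algo for r in records})
    algorithms = tuple(algorithms)
    if class_count is None:
        class_count = max(r.patt_ent_class for r in records)

    by_pattern: Dict[str, Dict[str, int]] = {}
    pattern_class: Dict[str, int] = {}
    for r in records:
        by_pattern.setdefault(r.pattern, {})[r.algo] = r.comp
        pattern_class[r.pattern] = r.patt_ent_class

    counts: Dict[int, Dict[str, List[int]]] = {
        k: {a: [0, 0, 0, 0] for a in algorithms} for k in range(1, class_count + 1)
    }
    class_patterns = {k: 0 for k in range(1, class_count + 1)}
    for pattern, cc in by_pattern.items():
        k = pattern_class[pattern]
        class_patterns[k] += 1
        for algo, q in assign_quartiles(cc).items():
            counts[k][algo][q - 1] += 1

    shares: Dict[int, Dict[str, Tuple[float, float, float, float]]] = {}
    for k in range(1, class_count + 1):
        n_k = class_patterns[k]
        shares[k] = {}
        for a in algorithms:
            if n_k == 0:
                shares[k][a] = (0.0, 0.0, 0.0, 0.0)
            else:
                shares[k][a] = tuple(c / n_k for c in counts[k][a])  # type: ignore[assignment]
    return QuartileShares(
        algorithms=algorithms,
        class_count=class_count,
        shares=shares,
        class_patterns=class_patterns,
    )


def rank_algorithms(shares: QuartileShares, class_index: int) -> List[str]:
    """Order a class's algorithms from most to least efficient.

    Descending first-quartile share, then descending q2 and q3, then
    ascending q4, then alphabetically.  An empty class has no evidence
    and yields an empty ranking.
    """
    if class_index not in shares.shares:
        raise KeyError(f"class {class_index} not present in shares")
    if shares.class_patterns.get(class_index, 0) == 0:
        return []
    cells = shares.shares[class_index]
    return sorted(
        shares.algorithms,
        key=lambda a: (-cells[a][0], -cells[a][1], -cells[a][2], cells[a][3], a),
    )


@dataclass(frozen=True)
class RankingModel:
    """A built domain model: scheme, shares, per-class rankings, provenance."""

    domain: str
    scheme: ClassScheme
    shares: QuartileShares
    rankings: Dict[int, List[str]]
    provenance: Dict[str, object] = field(default_factory=dict)


def build_model(
    text: str,
    patterns: Sequence[str],
    algorithms: Sequence[str] = ALGORITHM_IDS,
    domain: str = "",
    seed: Optional[int] = None,
    text_ids: Sequence[str] = (),
) -> RankingModel:
    """Run the full model-building pipeline on one domain text.

    Builds the class scheme from the campaign's own rounded entropies,
    runs the |patterns| x |algorithms| search campaign, aggregates
    quartile shares per class and ranks the algorithms.
    """
    rounded = sorted({round_entropy(shannon_entropy(p)) for p in patterns})
    scheme = build_class_scheme(rounded)
    records = run_campaign(text, patterns, algorithms, scheme=scheme)
    shares = aggregate_shares(
        records, class_count=scheme.class_count, algorithms=sorted(algorithms)
    )
    rankings = {
        k: rank_algorithms(shares, k) for k in range(1, scheme.class_count + 1)
    }
    provenance = {
        "seed": seed,
        "text_ids": list(text_ids),
        "n_patterns": len(set(patterns)),
    }
    return RankingModel(
        domain=domain,
        scheme=scheme,
        shares=shares,
        rankings=rankings,
        provenance=provenance,
    )


def predict(pattern: str, model: RankingModel) -> List[str]:
    """Rank algorithms for an unseen pattern via its entropy class.

    Entropies outside the model's range fall into the nearest class, so
    every nonempty-class prediction succeeds; a pattern landing in a
    class the campaign never populated returns an empty ranking.
    """
    h = round_entropy(shannon_entropy(pattern))
    k = assign_class(h, model.scheme)
    return list(model.rankings.get(k, []))


# ---------------------------------------------------------------------------
# serialization


def model_to_dict(model: RankingModel) -> Dict[str, object]:
    scheme = model.scheme
    classes = []
    for k in range(1, scheme.class_count + 1):
        classes.append(
            {
                "index": k,
                "label": scheme.labels[k - 1],
                "n_patterns": model.shares.class_patterns.get(k, 0),
                "shares": {
                    a: {
                        "q1": model.shares.shares[k][a][0],
                        "q2": model.shares.shares[k][a][1],
                        "q3": model.shares.shares[k][a][2],
                        "q4": model.shares.shares[k][a][3],
                    }
                    for a in model.shares.algorithms
                },
                "ranking": model.rankings.get(k, []),
            }
        )
    return {
        "domain": model.domain,
        "scheme": {
            "min": scheme.minimum,
            "max": scheme.maximum,
            "C": scheme.class_count,
            "h": scheme.width,
            "boundaries": list(scheme.boundaries),
            "labels": list(scheme.labels),
        },
        "classes": classes,
        "provenance": model.provenance,
    }


def model_from_dict(doc: Mapping[str, object]) -> RankingModel:
    s = doc["scheme"]  # type: ignore[index]
    scheme = ClassScheme(
        class_count=int(s["C"]),
        width=float(s["h"]),
        minimum=float(s["min"]),
        maximum=float(s["max"]),
        boundaries=tuple(float(b) for b in s["boundaries"]),
        labels=tuple(s.get("labels", [""] * int(s["C"]))),
    )
    classes = doc["classes"]  # type: ignore[index]
    algorithms = tuple(sorted(classes[0]["shares"].keys())) if classes else ()
    shares_map: Dict[int, Dict[str, Tuple[float, float, float, float]]] = {}
    class_patterns: Dict[int, int] = {}
    rankings: Dict[int, List[str]] = {}
    for c in classes:
        k = int(c["index"])
        class_patterns[k] = int(c["n_patterns"])
        shares_map[k] = {
            a: (
                float(v["q1"]),
                float(v["q2"]),
                float(v["q3"]),
                float(v["q4"]),
            )
            for a, v in c["shares"].items()
        }
        rankings[k] = list(c["ranking"])
    shares = QuartileShares(
        algorithms=algorithms,
        class_count=scheme.class_count,
        shares=shares_map,
        class_patterns=class_patterns,
    )
    return RankingModel(
        domain=str(doc.get("domain", "")),
        scheme=scheme,
        shares=shares,
        rankings=rankings,
        provenance=dict(doc.get("provenance", {})),  # type: ignore[arg-type]
    )


def save_model(model: RankingModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2), encoding="utf-8")


def load_model(path: str | Path) -> RankingModel:
    return model_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
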