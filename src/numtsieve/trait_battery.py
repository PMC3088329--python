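"""The eleven-trait numt screen.

Raw substitution counts are converted into eleven traits — codon
position percentages, nonsynonymous percentage, GpC-context share of
C->T changes, indel/stop counts, and 3rd-position transition/
transversion percentages plus GC content — and each is compared
against a published expectation range for authentic mtDNA.  A
haplotype set passes when all eleven traits sit inside their ranges;
any excursion flags the dataset as numt-suspect.

The expectation ranges are treated as authoritative constants: they
derive from reference datasets external to the screened alignment and
are not recomputed.  The score (chi-square inversion) confidence
interval on each observed proportion is attached for reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.stats import chi2

from .substitution_profile import SubstitutionCounts

__all__ = [
    "TRAIT_IDS",
    "TraitReference",
    "TraitResult",
    "TraitReport",
    "default_reference",
    "load_reference",
    "compute_traits",
    "evaluate",
    "proportion_ci",
]

TRAIT_IDS = (
    "pct_pos1",
    "pct_pos2",
    "pct_pos3",
    "pct_nonsyn",
    "pct_gc_to_gt_of_ct",
    "insertions",
    "deletions",
    "extra_stops",
    "pct_ts3",
    "pct_tv3",
    "gc_percent",
)

#: Human-readable row labels, in published-table order.
TRAIT_LABELS = {
    "pct_pos1": "1st codon position substitutions (%)",
    "pct_pos2": "2nd codon position substitutions (%)",
    "pct_pos3": "3rd codon position substitutions (%)",
    "pct_nonsyn": "Nonsynonymous substitutions (%)",
    "pct_gc_to_gt_of_ct": "GC>GT substitutions (% of C>T)",
    "insertions": "Insertions (count)",
    "deletions": "Deletions (count)",
    "extra_stops": "Additional stop codons (count)",
    "pct_ts3": "Transitions, 3rd codon position (%)",
    "pct_tv3": "Transversions, 3rd codon position (%)",
    "gc_percent": "GC content (%)",
}


@dataclass(frozen=True)
class TraitReference:
    """Expected range for one trait in authentic mtDNA.

    Interval traits pass when ``expected - margin <= observed <=
    expected + margin``; zero traits (``require_zero``) pass only at an
    observed count of exactly 0.
    """

    trait_id: str
    expected: float | None
    margin: float | None
    require_zero: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if self.trait_id not in TRAIT_IDS:
            raise ValueError(f"unknown trait_id {self.trait_id!r}")
        if self.require_zero:
            if self.expected is not None or self.margin is not None:
                raise ValueError("zero traits take no expected value or margin")
        else:
            if self.expected is None or self.margin is None or self.margin < 0:
                raise ValueError(
                    f"interval trait {self.trait_id} needs expected and margin >= 0"
                )


def default_reference() -> list[TraitReference]:
    """The published authentic-mtDNA expectation set for insect COI."""
    return [
        TraitReference("pct_pos1", 14.9, 9.4, source="codon position spectrum, insect mtDNA surveys"),
        TraitReference("pct_pos2", 4.5, 3.5, source="codon position spectrum, insect mtDNA surveys"),
        TraitReference("pct_pos3", 80.6, 21.0, source="codon position spectrum, insect mtDNA surveys"),
        TraitReference("pct_nonsyn", 7.47, 5.4, source="Drosophila subquinaria COI data"),
        TraitReference("pct_gc_to_gt_of_ct", 25.0, 14.0, source="nC>nT context spectra, unmethylated mtDNA"),
        TraitReference("insertions", None, None, require_zero=True, source="intact reading frame"),
        TraitReference("deletions", None, None, require_zero=True, source="intact reading frame"),
        TraitReference("extra_stops", None, None, require_zero=True, source="intact reading frame"),
        TraitReference("pct_ts3", 84.9, 18.1, source="insect mtDNA transition bias surveys"),
        TraitReference("pct_tv3", 15.1, 7.6, source="insect mtDNA transition bias surveys"),
        TraitReference("gc_percent", 28.66, 10.5, source="insect COI base composition"),
    ]


def load_reference(path) -> list[TraitReference]:
    """Load a custom reference set from YAML.

    Schema: a mapping of trait_id to either the string ``"zero"`` or a
    mapping with keys ``expected``, ``margin`` and optional ``source``.
    All eleven trait ids must be present.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    refs = []
    for trait_id in TRAIT_IDS:
        if trait_id not in raw:
            raise ValueError(f"reference file missing trait {trait_id!r}")
        entry = raw[trait_id]
        if entry == "zero":
            refs.append(TraitReference(trait_id, None, None, require_zero=True))
        else:
            refs.append(
                TraitReference(
                    trait_id,
                    float(entry["expected"]),
                    float(entry["margin"]),
                    source=str(entry.get("source", "")),
                )
            )
    return refs


def compute_traits(counts: SubstitutionCounts) -> dict[str, float | None]:
    """Observed trait values from raw counts.

    Percentage traits with a zero denominator are ``None`` ("not
    evaluable"); the companion key ``ts_tv_ratio`` is the overall
    transition/transversion ratio (``inf`` when no transversions were
    seen) and carries no acceptance range.
    """
    t: dict[str, float | None] = {}
    total = counts.total
    if total >= 1:
        t["pct_pos1"] = 100.0 * counts.pos1 / total
        t["pct_pos2"] = 100.0 * counts.pos2 / total
        t["pct_pos3"] = 100.0 * counts.pos3 / total
        t["pct_nonsyn"] = 100.0 * counts.nonsyn / total
    else:
        t["pct_pos1"] = t["pct_pos2"] = t["pct_pos3"] = t["pct_nonsyn"] = None
    denom_ct = counts.c_to_t_with_context
    t["pct_gc_to_gt_of_ct"] = (
        100.0 * counts.gc_to_gt / denom_ct if denom_ct >= 1 else None
    )
    if counts.pos3 >= 1:
        t["pct_ts3"] = 100.0 * counts.ts3 / counts.pos3
        t["pct_tv3"] = 100.0 * counts.tv3 / counts.pos3
    else:
        t["pct_ts3"] = t["pct_tv3"] = None
    t["insertions"] = float(counts.insertions)
    t["deletions"] = float(counts.deletions)
    t["extra_stops"] = float(counts.extra_stops)
    t["gc_percent"] = counts.gc_percent
    if counts.tv_all >= 1:
        t["ts_tv_ratio"] = counts.ts_all / counts.tv_all
    else:
        t["ts_tv_ratio"] = math.inf if counts.ts_all >= 1 else None
    return t


@dataclass(frozen=True)
class TraitResult:
    trait_id: str
    observed: float | None
    interval: tuple[float, float] | None  # None for zero traits
    passed: bool
    evaluable: bool
    score_ci: tuple[float, float] | None = None  # reporting-only CI on observed

    @property
    def label(self) -> str:
        return TRAIT_LABELS[self.trait_id]


@dataclass
class TraitReport:
    """Per-trait outcomes plus the overall verdict.

    ``verdict`` is "PASS" (consistent with authentic mtDNA) when the
    required number of traits pass — all eleven in strict mode — and
    "FLAG" (numt-suspect) otherwise.
    """

    results: list[TraitResult]
    ts_tv_ratio: float | None
    verdict: str
    failing_traits: list[str]
    required_passes: int
    metadata: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.verdict == "PASS"


def proportion_ci(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Score confidence interval for a binomial proportion, in percent.

    Inverts the one-degree-of-freedom chi-square goodness-of-fit
    statistic: the interval is every p for which ``(x - n p)^2 /
    (n p (1-p)) <= chi2_{1, 1-alpha}``, which has the closed-form
    solution below (the Wilson score interval).
    """
    if n < 1:
        raise ValueError("proportion CI undefined for n = 0")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z2 = chi2.ppf(1 - alpha, df=1)
    p = successes / n
    denom = 1 + z2 / n
    center = (p + z2 / (2 * n)) / denom
    half = math.sqrt(z2) * math.sqrt(p * (1 - p) / n + z2 / (4 * n * n)) / denom
    return (100 * max(0.0, center - half), 100 * min(1.0, center + half))


def _score_ci_for(trait_id: str, counts: SubstitutionCounts, alpha: float):
    """(successes, n) pairs backing each percentage trait, for annotation."""
    pairs = {
        "pct_pos1": (counts.pos1, counts.total),
        "pct_pos2": (counts.pos2, counts.total),
        "pct_pos3": (counts.pos3, counts.total),
        "pct_nonsyn": (counts.nonsyn, counts.total),
        "pct_gc_to_gt_of_ct": (counts.gc_to_gt, counts.c_to_t_with_context),
        "pct_ts3": (counts.ts3, counts.pos3),
        "pct_tv3": (counts.tv3, counts.pos3),
    }
    if trait_id not in pairs:
        return None
    x, n = pairs[trait_id]
    return proportion_ci(x, n, alpha) if n >= 1 else None


def evaluate(
    traits: Mapping[str, float | None],
    references: Sequence[TraitReference] | None = None,
    counts: SubstitutionCounts | None = None,
    alpha: float = 0.05,
    relaxed_k: int | None = None,
) -> TraitReport:
    """Compare observed traits against the reference ranges.

    Not-evaluable traits (zero denominators) pass with an annotation:
    the absence of, say, C->T events is no evidence of nuclear origin.
    ``relaxed_k`` lowers the verdict requirement to k passing traits
    (exploratory use only); the default strict mode requires all 11.
    """
    refs = list(references) if references is not None else default_reference()
    ref_ids = [r.trait_id for r in refs]
    if sorted(ref_ids) != sorted(TRAIT_IDS):
        missing = set(TRAIT_IDS) - set(ref_ids)
        extra = set(ref_ids) - set(TRAIT_IDS)
        raise ValueError(
            f"reference set must cover exactly the 11 traits; missing={sorted(missing)} extra={sorted(extra)}"
        )
    results = []
    for ref in refs:
        if ref.trait_id not in traits:
            raise ValueError(f"trait map missing {ref.trait_id!r}")
        observed = traits[ref.trait_id]
        evaluable = observed is not None
        if ref.require_zero:
            interval = None
            passed = evaluable and observed == 0
        elif not evaluable:
            interval = (ref.expected - ref.margin, ref.expected + ref.margin)
            passed = True  # not evaluable: auto-pass with annotation
        else:
            interval = (ref.expected - ref.margin, ref.expected + ref.margin)
            passed = interval[0] <= observed <= interval[1]
        score_ci = (
            _score_ci_for(ref.trait_id, counts, alpha) if counts is not None else None
        )
        results.append(
            TraitResult(
                trait_id=ref.trait_id,
                observed=observed,
                interval=interval,
                passed=passed,
                evaluable=evaluable,
                score_ci=score_ci,
            )
        )
    n_pass = sum(r.passed for r in results)
    required = len(results) if relaxed_k is None else relaxed_k
    verdict = "PASS" if n_pass >= required else "FLAG"
    return TraitReport(
        results=results,
        ts_tv_ratio=traits.get("ts_tv_ratio"),
        verdict=verdict,
        failing_traits=[r.trait_id for r in results if not r.passed],
        required_passes=required,
        metadata={"alpha": alpha, "mode": "strict" if relaxed_k is None else f"relaxed-{relaxed_k}"},
    )
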