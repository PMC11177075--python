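"""Seeded generator of synthetic Utstein-style OHCA cohorts.

The generator emulates the statistical structure of a nationwide registry
cohort without prehospital ROSC: records are drawn *stratum-first* — each
record's ABC score is sampled from a configured score distribution, concrete
component fields (age, witnessed status, no-flow time, rhythm, PAD) are then
realised consistently with that stratum, and the 1-month CPC category is
drawn from per-score outcome probabilities.  Stratum-first construction
makes the score marginal match its target exactly in expectation, which is
the property the downstream discrimination analyses depend on; inter-variable
correlations beyond those the strata impose are not modelled.

Deliberately ineligible records (minors, external causes, missing fields,
prehospital ROSC, derivation-region cases, transition-year cases) can be
appended to exercise the selection funnel.  Each contamination class draws
from its own RNG substream spawned from the root seed, so switching
contamination on or off never perturbs the eligible records, and every
record's intended fate is encoded in its ``record_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .records import Cause, Cpc, FirstRhythm, Region, UtsteinRecord
from .selection import FILTER_STEPS

_EXTERNAL_CAUSES = (
    Cause.EXTERNAL_TRAUMA,
    Cause.EXTERNAL_HYPOTHERMIA,
    Cause.EXTERNAL_DROWNING,
    Cause.EXTERNAL_POISONING,
    Cause.EXTERNAL_OTHER,
)

_TRANSITION_YEARS = (2010, 2011, 2015, 2016, 2020, 2021)

# the three component patterns realising score 1 and score 2
_PATTERNS_BY_SCORE = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(1, 1, 0), (1, 0, 1), (0, 1, 1)],
    3: [(1, 1, 1)],
}


class SyntheticConfigError(ValueError):
    """An infeasible or inconsistent generator configuration."""


@dataclass
class ComponentStyle:
    """How each score stratum is realised as concrete Utstein fields.

    Ages are truncated normals per A-component arm (the old arm centred near
    the registry's median of ~81 years); no-flow times among B=1 records are
    a discrete 0-5 min distribution with median 3, and witnessed-but-late
    records get an exponential tail over 6-30 min.  ``pad_given_c`` splits
    the cardiogram component between shockable first rhythm and bystander
    public-access defibrillation.
    """

    age_young_mean: float = 60.0
    age_young_sd: float = 10.0
    age_old_mean: float = 81.0
    age_old_sd: float = 8.0
    witnessed_given_not_b: float = 0.21
    no_flow_weights_b1: tuple[float, ...] = (0.2, 0.1, 0.1, 0.2, 0.2, 0.2)
    no_flow_tail_scale: float = 5.0
    pad_given_c: float = 0.07
    vt_fraction_shockable: float = 0.10
    pad_rhythm_shockable: float = 0.5
    spontaneous_rhythm_given_not_c: float = 0.01
    asystole_given_not_c: float = 0.60
    cpc1_within_favourable: float = 0.5
    cpc3_within_unfavourable: float = 0.5

    def validate(self) -> None:
        probs = {
            "witnessed_given_not_b": self.witnessed_given_not_b,
            "pad_given_c": self.pad_given_c,
            "vt_fraction_shockable": self.vt_fraction_shockable,
            "pad_rhythm_shockable": self.pad_rhythm_shockable,
            "spontaneous_rhythm_given_not_c": self.spontaneous_rhythm_given_not_c,
            "asystole_given_not_c": self.asystole_given_not_c,
            "cpc1_within_favourable": self.cpc1_within_favourable,
            "cpc3_within_unfavourable": self.cpc3_within_unfavourable,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SyntheticConfigError(f"{name} must be a probability, got {p}")
        w = np.asarray(self.no_flow_weights_b1, dtype=float)
        if len(w) != 6 or (w < 0).any() or w.sum() <= 0:
            raise SyntheticConfigError(
                "no_flow_weights_b1 must be 6 non-negative weights over 0..5 min"
            )


@dataclass
class Contamination:
    """Rates of deliberately ineligible records, per selection-funnel step."""

    under_18: float = 0.0
    external_cause: float = 0.0
    missing_fields: float = 0.0
    outcome_unknown: float = 0.0
    prehospital_rosc: float = 0.0
    kanto: float = 0.0
    transition_year: float = 0.0

    _FATES = {
        "under_18": "not_attempted_or_under_18",
        "external_cause": "external_cause",
        "missing_fields": "score_not_computable",
        "outcome_unknown": "outcome_unknown",
        "prehospital_rosc": "prehospital_rosc",
        "kanto": "kanto_region",
        "transition_year": "transition_year",
    }

    def rates_by_fate(self) -> dict[str, float]:
        return {fate: getattr(self, attr) for attr, fate in self._FATES.items()}

    def validate(self) -> None:
        for attr in self._FATES:
            rate = getattr(self, attr)
            if not 0.0 <= rate <= 1.0:
                raise SyntheticConfigError(f"contamination rate {attr} = {rate}")


@dataclass
class SyntheticConfig:
    """All distributional parameters for one guideline group's cohort."""

    n_records: int = 10_000
    score_distribution: tuple[float, float, float, float] = (0.56, 0.35, 0.075, 0.015)
    outcome_probabilities: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {
            0: (0.0018, 0.008),
            1: (0.0058, 0.018),
            2: (0.0293, 0.045),
            3: (0.0954, 0.105),
        }
    )
    years: tuple[int, ...] = (2007, 2008, 2009)
    component_style: ComponentStyle = field(default_factory=ComponentStyle)
    contamination: Contamination = field(default_factory=Contamination)
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 0:
            raise SyntheticConfigError("n_records must be >= 0")
        dist = np.asarray(self.score_distribution, dtype=float)
        if len(dist) != 4 or (dist < 0).any():
            raise SyntheticConfigError("score_distribution needs 4 probabilities")
        if abs(dist.sum() - 1.0) > 1e-9:
            raise SyntheticConfigError(
                f"score_distribution sums to {dist.sum()!r}, not 1"
            )
        for s in range(4):
            if s not in self.outcome_probabilities:
                raise SyntheticConfigError(f"no outcome probabilities for score {s}")
            p12, p34 = self.outcome_probabilities[s]
            if not (0 <= p12 <= 1 and 0 <= p34 <= 1 and p12 + p34 <= 1):
                raise SyntheticConfigError(
                    f"outcome probabilities for score {s}: p12={p12}, p34={p34}"
                )
        if not self.years:
            raise SyntheticConfigError("years must be non-empty")
        self.component_style.validate()
        self.contamination.validate()

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_mapping(cls, data: dict) -> "SyntheticConfig":
        kwargs = dict(data)
        if "score_distribution" in kwargs:
            kwargs["score_distribution"] = tuple(kwargs["score_distribution"])
        if "years" in kwargs:
            kwargs["years"] = tuple(kwargs["years"])
        if "outcome_probabilities" in kwargs:
            kwargs["outcome_probabilities"] = {
                int(k): tuple(v) for k, v in kwargs["outcome_probabilities"].items()
            }
        if "component_style" in kwargs and isinstance(kwargs["component_style"], dict):
            style = kwargs["component_style"]
            if "no_flow_weights_b1" in style:
                style["no_flow_weights_b1"] = tuple(style["no_flow_weights_b1"])
            kwargs["component_style"] = ComponentStyle(**style)
        if "contamination" in kwargs and isinstance(kwargs["contamination"], dict):
            kwargs["contamination"] = Contamination(**kwargs["contamination"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_mapping(data or {})


def load_bundled_config(name: str) -> SyntheticConfig:
    """Load one of the shipped group configs ('g2005', 'g2010', 'g2015')."""
    path = Path(__file__).parent / "configs" / f"{name}.yaml"
    if not path.exists():
        raise FileNotFoundError(f"no bundled config named {name!r}")
    return SyntheticConfig.from_yaml(path)


# ---------------------------------------------------------------------------
# sampling


def _draw_eligible(
    config: SyntheticConfig, rng: np.random.Generator, count: int, id_prefix: str
) -> list[UtsteinRecord]:
    """Vectorised draw of `count` records eligible for every funnel step."""
    if count == 0:
        return []
    style = config.component_style
    scores = rng.choice(4, size=count, p=np.asarray(config.score_distribution))

    # component pattern per record
    a = np.zeros(count, dtype=bool)
    b = np.zeros(count, dtype=bool)
    c = np.zeros(count, dtype=bool)
    for s in range(4):
        idx = np.flatnonzero(scores == s)
        if idx.size == 0:
            continue
        patterns = np.asarray(_PATTERNS_BY_SCORE[s])
        chosen = patterns[rng.integers(0, len(patterns), size=idx.size)]
        a[idx], b[idx], c[idx] = chosen[:, 0] == 1, chosen[:, 1] == 1, chosen[:, 2] == 1

    ages = np.where(
        a,
        np.clip(np.rint(rng.normal(style.age_young_mean, style.age_young_sd, count)), 18, 70),
        np.clip(np.rint(rng.normal(style.age_old_mean, style.age_old_sd, count)), 71, 105),
    ).astype(int)

    witnessed = np.where(
        b, True, rng.random(count) < style.witnessed_given_not_b
    )
    nf_weights = np.asarray(style.no_flow_weights_b1, dtype=float)
    nf_weights = nf_weights / nf_weights.sum()
    no_flow = np.where(
        b,
        rng.choice(6, size=count, p=nf_weights),
        np.minimum(30, 6 + np.floor(rng.exponential(style.no_flow_tail_scale, count))),
    ).astype(float)

    pad = c & (rng.random(count) < style.pad_given_c)
    shockable = c & ~pad
    vt = shockable & (rng.random(count) < style.vt_fraction_shockable)
    pad_shock = pad & (rng.random(count) < style.pad_rhythm_shockable)
    spont = ~c & (rng.random(count) < style.spontaneous_rhythm_given_not_c)
    asys = ~c & ~spont & (rng.random(count) < style.asystole_given_not_c)

    p12 = np.array([config.outcome_probabilities[s][0] for s in range(4)])[scores]
    p34 = np.array([config.outcome_probabilities[s][1] for s in range(4)])[scores]
    u = rng.random(count)
    favourable = u < p12
    unfavourable = (~favourable) & (u < p12 + p34)
    cpc_split = rng.random(count)

    years = np.asarray(config.years)[rng.integers(0, len(config.years), size=count)]

    records = []
    for i in range(count):
        if pad[i]:
            rhythm = FirstRhythm.VF if pad_shock[i] else FirstRhythm.PEA
        elif c[i]:
            rhythm = FirstRhythm.VT if vt[i] else FirstRhythm.VF
        elif spont[i]:
            rhythm = FirstRhythm.SPONTANEOUS_CIRCULATION
        else:
            rhythm = FirstRhythm.ASYSTOLE if asys[i] else FirstRhythm.PEA
        if favourable[i]:
            cpc = Cpc.CPC1 if cpc_split[i] < style.cpc1_within_favourable else Cpc.CPC2
        elif unfavourable[i]:
            cpc = Cpc.CPC3 if cpc_split[i] < style.cpc3_within_unfavourable else Cpc.CPC4
        else:
            cpc = Cpc.CPC5
        is_witnessed = bool(witnessed[i])
        records.append(
            UtsteinRecord(
                record_id=f"{id_prefix}-{i:07d}",
                age=int(ages[i]),
                cause=Cause.INTERNAL,
                witnessed=is_witnessed,
                no_flow_time=float(no_flow[i]) if is_witnessed else None,
                first_rhythm=rhythm,
                pad_performed=bool(pad[i]),
                prehospital_rosc=False,
                resuscitation_attempted=True,
                region=Region.OTHER,
                year=int(years[i]),
                cpc=cpc,
            )
        )
    return records


def _corrupt(
    records: list[UtsteinRecord], fate: str, rng: np.random.Generator
) -> list[UtsteinRecord]:
    """Make each record fail exactly its intended funnel step."""
    for rec in records:
        if fate == "not_attempted_or_under_18":
            if rng.random() < 0.5:
                rec.age = int(rng.integers(1, 18))
            else:
                rec.resuscitation_attempted = False
        elif fate == "external_cause":
            rec.cause = _EXTERNAL_CAUSES[rng.integers(0, len(_EXTERNAL_CAUSES))]
        elif fate == "score_not_computable":
            if rng.random() < 0.5:
                rec.witnessed = None
                rec.no_flow_time = None
            else:
                rec.first_rhythm = None
                rec.pad_performed = False
        elif fate == "outcome_unknown":
            rec.cpc = Cpc.UNKNOWN
        elif fate == "prehospital_rosc":
            rec.prehospital_rosc = True
        elif fate == "kanto_region":
            rec.region = Region.KANTO
        elif fate == "transition_year":
            rec.year = int(_TRANSITION_YEARS[rng.integers(0, len(_TRANSITION_YEARS))])
        else:  # pragma: no cover
            raise ValueError(f"unknown fate {fate!r}")
    return records


def generate_cohort(config: SyntheticConfig) -> list[UtsteinRecord]:
    """Generate a cohort: eligible records plus appended contamination.

    ``config.n_records`` eligible records are drawn, then each contamination
    class appends a Binomial(n_records, rate) number of records that fail
    exactly that funnel step.  Every record's intended fate is the second
    token of its ``record_id`` (``eligible`` or a funnel-step name), so the
    selection funnel's tallies can be checked against the generator's
    bookkeeping record by record.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(1 + len(FILTER_STEPS))
    rng_eligible = np.random.default_rng(streams[0])

    records = _draw_eligible(
        config, rng_eligible, config.n_records, f"s{config.seed}-eligible"
    )
    rates = config.contamination.rates_by_fate()
    for k, fate in enumerate(FILTER_STEPS):
        rate = rates[fate]
        if rate <= 0.0:
            continue
        rng = np.random.default_rng(streams[1 + k])
        m = int(rng.binomial(config.n_records, rate))
        extra = _draw_eligible(config, rng, m, f"s{config.seed}-{fate}")
        records.extend(_corrupt(extra, fate, rng))
    return records


def intended_fate(record: UtsteinRecord) -> str:
    """Fate label encoded in a synthetic record's id."""
    return record.record_id.split("-", 1)[1].rsplit("-", 1)[0]


def intended_exclusion_tallies(records: Sequence[UtsteinRecord]) -> dict[str, int]:
    """Generator-side bookkeeping: intended funnel tallies of a cohort."""
    tallies = {step: 0 for step in FILTER_STEPS}
    n_eligible = 0
    for rec in records:
        fate = intended_fate(rec)
        if fate == "eligible":
            n_eligible += 1
        else:
            tallies[fate] += 1
    return {"n_eligible": n_eligible, **tallies}


def expected_auroc(config: SyntheticConfig) -> float:
    """Tie-corrected AUROC implied by the configured distributions.

    Applies the rank form to the expected cell masses: with score mass
    ``pi_s`` and favourable probability ``p_s``, positive mass is
    ``pi_s * p_s`` and negative mass ``pi_s * (1 - p_s)``.
    """
    config.validate()
    pi = np.asarray(config.score_distribution, dtype=float)
    p12 = np.array([config.outcome_probabilities[s][0] for s in range(4)])
    pos = pi * p12
    neg = pi * (1 - p12)
    P, Q = pos.sum(), neg.sum()
    if P <= 0 or Q <= 0:
        raise SyntheticConfigError("expected positives and negatives must be > 0")
    wins = sum(pos[s] * neg[t] for s in range(4) for t in range(4) if s > t)
    ties = float(np.dot(pos, neg))
    return float((wins + 0.5 * ties) / (P * Q))
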