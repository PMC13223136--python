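"""Domain types and tabular I/O for irregular multi-modal perioperative episodes.

One observation is an *event triplet* ``(value, t_sec, modality)``; an episode
is a time-sorted sequence of triplets plus static patient features. Timestamps
are seconds relative to anesthetic induction (t = 0 at induction) — relative
time is what the continuous positional encoding consumes; a helper converts
from epoch timestamps.

Lab modalities are the four inflammatory markers (IL-6, CRP, TNF-α, IL-10).
A dedicated ``lab_ordered_missing`` token (value 1 at the order time) encodes
the "ordered but unresulted" pattern as its own informative signal.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MODALITIES", "LAB_MODALITIES", "CYTOKINES", "ModalityVocabulary",
    "EventTriplet", "StaticFeatures", "Episode", "Standardizer",
    "SchemaError", "read_episodes", "write_episodes", "fit_standardizer",
    "apply_standardizer", "mask_labs", "epoch_to_relative",
]

# Order fixes the stable integer codes (tie-break order at equal timestamps).
MODALITIES: tuple[str, ...] = (
    "map", "hr", "spo2", "temp", "resp_rate", "urine_output",
    "propofol_rate", "ketamine_rate", "vasopressor_rate", "fluid_balance",
    "fentanyl_cum", "depth_proxy",
    "il6", "crp", "tnfa", "il10",
    "lab_ordered_missing",
)
CYTOKINES: tuple[str, ...] = ("il6", "crp", "tnfa", "il10")
LAB_MODALITIES: tuple[str, ...] = CYTOKINES
DRUG_MODALITIES: tuple[str, ...] = ("propofol_rate", "ketamine_rate",
                                    "vasopressor_rate")

BURN_MECHANISMS = ("flame", "scald", "chemical", "electrical")


class SchemaError(ValueError):
    """Input table violates the documented column/vocabulary schema."""


@dataclass(frozen=True)
class ModalityVocabulary:
    """Ordered modality tokens with stable integer codes."""

    tokens: tuple[str, ...] = MODALITIES

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise SchemaError("modality tokens must be unique")

    def code(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            raise SchemaError(f"unknown modality token {token!r}") from None

    def __contains__(self, token: str) -> bool:
        return token in self.tokens

    def __len__(self) -> int:
        return len(self.tokens)

    def to_dict(self) -> dict:
        return {"tokens": list(self.tokens)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModalityVocabulary":
        return cls(tuple(d["tokens"]))


DEFAULT_VOCAB = ModalityVocabulary()


@dataclass(frozen=True)
class EventTriplet:
    value: float
    t_sec: float
    modality: str

    def __post_init__(self):
        if not np.isfinite(self.t_sec):
            raise SchemaError("event timestamp must be finite")
        if not np.isfinite(self.value):
            raise SchemaError(
                "event value must be finite; use the lab_ordered_missing "
                "modality for ordered-but-unresulted labs")


@dataclass(frozen=True)
class StaticFeatures:
    age: float
    sex: int            # 1 = female
    bmi: float
    cci: int
    tbsa: float         # % total body surface area burned
    mechanism: str
    inhalation: int
    baux: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not 0.0 <= self.tbsa <= 100.0:
            raise SchemaError(f"tbsa must be in [0,100], got {self.tbsa}")
        if self.mechanism not in BURN_MECHANISMS:
            raise SchemaError(f"unknown burn mechanism {self.mechanism!r}")
        if self.baux is None:
            object.__setattr__(self, "baux", self.age + self.tbsa)
        elif abs(self.baux - (self.age + self.tbsa)) > 1e-6:
            raise SchemaError("baux must equal age + tbsa")

    def as_vector(self) -> np.ndarray:
        mech = [1.0 if self.mechanism == m else 0.0
                for m in BURN_MECHANISMS[1:]]  # flame is reference level
        return np.array([self.age, self.sex, self.bmi, self.cci, self.tbsa,
                         self.inhalation, self.baux] + mech)

    @staticmethod
    def vector_names() -> list[str]:
        return (["age", "sex", "bmi", "cci", "tbsa", "inhalation", "baux"]
                + [f"mech_{m}" for m in BURN_MECHANISMS[1:]])


def _sort_key(vocab: ModalityVocabulary):
    def key(e: EventTriplet):
        return (e.t_sec, vocab.code(e.modality))
    return key


@dataclass
class Episode:
    """One perioperative record: statics + time-ordered event triplets.

    Events are kept sorted by (timestamp, modality code); the tie-break on the
    modality code makes repeated reads reproduce identical sequences.
    """

    episode_id: str
    static: StaticFeatures
    events: list[EventTriplet]
    exposure: str = "propofol-only"   # or "propofol+ketamine"
    vocab: ModalityVocabulary = field(default_factory=lambda: DEFAULT_VOCAB)

    def __post_init__(self):
        for e in self.events:
            if e.modality not in self.vocab:
                raise SchemaError(f"unknown modality token {e.modality!r}")
        self.events = sorted(self.events, key=_sort_key(self.vocab))

    def values(self, modality: str) -> np.ndarray:
        return np.array([e.value for e in self.events
                         if e.modality == modality])

    def times(self, modality: str) -> np.ndarray:
        return np.array([e.t_sec for e in self.events
                         if e.modality == modality])

    def lab_events(self) -> list[EventTriplet]:
        return [e for e in self.events if e.modality in LAB_MODALITIES]

    def analysis_eligible(self) -> bool:
        """≥2 inflammatory lab results in the (6 h, 24 h] post-induction window."""
        n = sum(1 for e in self.lab_events() if 6 * 3600 < e.t_sec <= 24 * 3600)
        return n >= 2

    def subset_before(self, t_sec: float) -> "Episode":
        return Episode(self.episode_id, self.static,
                       [e for e in self.events if e.t_sec <= t_sec],
                       self.exposure, self.vocab)


def epoch_to_relative(unix_ts: Sequence[float], induction_unix: float) -> np.ndarray:
    """Convert absolute epoch timestamps to seconds since induction."""
    return np.asarray(unix_ts, dtype=float) - float(induction_unix)


# --------------------------------------------------------------------------
# Tabular I/O

_EVENT_COLS = ["episode_id", "t_sec", "modality", "value"]
_STATIC_COLS = ["episode_id", "age", "sex", "bmi", "cci", "tbsa",
                "mechanism", "inhalation", "baux", "exposure"]


def write_episodes(episodes: Iterable[Episode]):
    """Serialize to (events table, static table) DataFrames.

    ``read_episodes`` on the output reproduces the episodes exactly.
    """
    ev_rows, st_rows = [], []
    for ep in episodes:
        for e in ep.events:
            ev_rows.append((ep.episode_id, e.t_sec, e.modality, e.value))
        s = ep.static
        st_rows.append((ep.episode_id, s.age, s.sex, s.bmi, s.cci, s.tbsa,
                        s.mechanism, s.inhalation, s.baux, ep.exposure))
    events = pd.DataFrame(ev_rows, columns=_EVENT_COLS)
    static = pd.DataFrame(st_rows, columns=_STATIC_COLS)
    return events, static


def read_episodes(events_table, static_table,
                  vocab: ModalityVocabulary = DEFAULT_VOCAB) -> list[Episode]:
    """Parse (events, static) tables — paths or DataFrames — into Episodes.

    Unsorted rows are sorted (never rejected); unknown modality tokens and
    missing columns raise :class:`SchemaError` naming the offender.
    """
    if not isinstance(events_table, pd.DataFrame):
        events_table = pd.read_csv(events_table)
    if not isinstance(static_table, pd.DataFrame):
        static_table = pd.read_csv(static_table)
    for col in _EVENT_COLS:
        if col not in events_table.columns:
            raise SchemaError(f"events table missing required column {col!r}")
    for col in _STATIC_COLS:
        if col not in static_table.columns:
            raise SchemaError(f"static table missing required column {col!r}")
    bad = set(events_table["modality"]) - set(vocab.tokens)
    if bad:
        raise SchemaError(f"unknown modality token(s): {sorted(bad)}")

    grouped = {k: g for k, g in events_table.groupby("episode_id", sort=False)}
    episodes = []
    for row in static_table.itertuples(index=False):
        st = StaticFeatures(age=row.age, sex=int(row.sex), bmi=row.bmi,
                            cci=int(row.cci), tbsa=row.tbsa,
                            mechanism=row.mechanism,
                            inhalation=int(row.inhalation), baux=row.baux)
        g = grouped.get(row.episode_id)
        events = [] if g is None else [
            EventTriplet(value=v, t_sec=t, modality=m)
            for t, m, v in zip(g["t_sec"], g["modality"], g["value"])]
        episodes.append(Episode(str(row.episode_id), st, events, row.exposure,
                                vocab))
    return episodes


# --------------------------------------------------------------------------
# Standardization

@dataclass
class Standardizer:
    """Per-modality location/scale, estimated once on the training split.

    Population standard deviation; a zero-variance modality gets scale 1 with
    a warning so degenerate synthetic configs never divide by zero. Statics
    get their own location/scale vector.
    """

    loc: dict[str, float]
    scale: dict[str, float]
    static_loc: np.ndarray
    static_scale: np.ndarray

    def transform_value(self, modality: str, value):
        return (value - self.loc[modality]) / self.scale[modality]

    def inverse_value(self, modality: str, z):
        return z * self.scale[modality] + self.loc[modality]

    def transform_static(self, vec: np.ndarray) -> np.ndarray:
        return (vec - self.static_loc) / self.static_scale

    def to_dict(self) -> dict:
        return {"loc": dict(self.loc), "scale": dict(self.scale),
                "static_loc": self.static_loc.tolist(),
                "static_scale": self.static_scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(d["loc"], d["scale"], np.array(d["static_loc"]),
                   np.array(d["static_scale"]))


def fit_standardizer(episodes: Sequence[Episode],
                     vocab: ModalityVocabulary = DEFAULT_VOCAB) -> Standardizer:
    loc, scale = {}, {}
    for m in vocab.tokens:
        if m == "lab_ordered_missing":   # indicator: constant by construction
            loc[m], scale[m] = 0.0, 1.0
            continue
        vals = np.concatenate([ep.values(m) for ep in episodes]) \
            if episodes else np.array([])
        if vals.size == 0:
            loc[m], scale[m] = 0.0, 1.0
            continue
        loc[m] = float(vals.mean())
        sd = float(vals.std())          # population SD
        if sd == 0.0:
            warnings.warn(f"modality {m!r} has zero variance; scale set to 1")
            sd = 1.0
        scale[m] = sd
    svecs = np.array([ep.static.as_vector() for ep in episodes])
    sloc = svecs.mean(axis=0)
    sscale = svecs.std(axis=0)
    sscale[sscale == 0.0] = 1.0
    return Standardizer(loc, scale, sloc, sscale)


def apply_standardizer(std: Standardizer,
                       episodes: Sequence[Episode]) -> list[Episode]:
    """Apply frozen parameters; never re-estimates."""
    out = []
    for ep in episodes:
        events = [dataclasses.replace(
            e, value=std.transform_value(e.modality, e.value))
            for e in ep.events]
        out.append(Episode(ep.episode_id, ep.static, events, ep.exposure,
                           ep.vocab))
    return out


# --------------------------------------------------------------------------
# Missingness stress tool

def mask_labs(episodes: Sequence[Episode], fraction: float,
              seed: int) -> list[Episode]:
    """Remove exactly round(fraction · n_lab_events) lab events uniformly at
    random across the cohort; non-lab events are untouched."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0,1), got {fraction}")
    rng = np.random.default_rng(seed)
    index = [(i, j) for i, ep in enumerate(episodes)
             for j, e in enumerate(ep.events) if e.modality in LAB_MODALITIES]
    n_drop = round(fraction * len(index))
    dropped = {index[int(k)] for k in rng.permutation(len(index))[:n_drop]}
    out = []
    for i, ep in enumerate(episodes):
        events = [e for j, e in enumerate(ep.events) if (i, j) not in dropped]
        out.append(Episode(ep.episode_id, ep.static, events, ep.exposure,
                           ep.vocab))
    return out
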