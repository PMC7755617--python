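"""Normative reference ranges and subject flagging.

A normative model stores, per metric (global volumes, global qT2, the two
L:R ratios, and per-bin profile values at matched normalised long-axis
positions), the healthy-cohort mean and SD; the reference band is always
mean +/- 1.96 SD, i.e. the central 95% interval under a Gaussian model with
no covariate adjustment.

A published default model ships with the package for the two ratio metrics
(volume ratio band [88.9, 110.6]%, qT2 ratio band [93.7, 104.2]%, from a
reference cohort of 111 healthy adults on a single 3T protocol); absolute
volume and qT2 norms are scanner- and protocol-specific and must be built
from a local cohort.

Flagging of an individual subject is decision support, clearly machine
advice: each metric is flagged low/high outside its band, and an overall
impression is derived with an explicit aggregation rule (abnormal ratio ->
the implicated side; normal ratios with both sides' absolute values
abnormal -> bilateral).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np

from .morphometry_profiles import GlobalMetrics, HippocampusProfile

__all__ = [
    "BAND_MULTIPLIER",
    "NormativeEntry",
    "NormativeModel",
    "FlagSet",
    "build_normative",
    "reference_band",
    "flag_subject",
    "default_ratio_model",
]

#: central-95% Gaussian band half-width in SD units
BAND_MULTIPLIER = 1.96
#: minimum cohort size to build a model; SD estimates below this are unstable
DEFAULT_MIN_N = 20

GLOBAL_METRICS = ("vol_left", "vol_right", "qt2_left", "qt2_right",
                  "lr_vol_ratio_pct", "lr_qt2_ratio_pct")

#: published normative ranges for the ratio metrics (% scale)
PUBLISHED_VOL_RATIO_BAND = (88.9, 110.6)
PUBLISHED_QT2_RATIO_BAND = (93.7, 104.2)


@dataclass
class NormativeEntry:
    """Mean/SD of one metric over the reference cohort, with its 95% band."""

    metric: str
    mean: float
    sd: float
    n: int
    lo: float = field(init=False)
    hi: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        self.lo = self.mean - BAND_MULTIPLIER * self.sd
        self.hi = self.mean + BAND_MULTIPLIER * self.sd

    @classmethod
    def from_band(cls, metric: str, lo: float, hi: float, n: int) -> "NormativeEntry":
        """Back-derive mean/SD from a published mean +/- 1.96 SD band."""
        return cls(metric=metric, mean=(lo + hi) / 2.0, sd=(hi - lo) / (2.0 * BAND_MULTIPLIER), n=n)


@dataclass
class NormativeModel:
    """Per-metric and per-bin normative entries plus provenance.

    ``profiles`` maps side -> metric ('area_mm2' | 'qt2_ms') -> dict with
    'positions', 'mean', 'sd' arrays at matched normalised arc positions.
    """

    entries: dict[str, NormativeEntry]
    profiles: dict[str, dict[str, dict[str, np.ndarray]]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return next(iter(self.entries.values())).n if self.entries else 0

    @property
    def n_bins(self) -> int | None:
        for side in self.profiles.values():
            for metric in side.values():
                return len(metric["positions"])
        return None

    def to_json(self, path: str | None = None) -> str:
        doc = {
            "schema": "hippoquant-normative/1",
            "provenance": self.provenance,
            "entries": {
                k: {"metric": e.metric, "mean": e.mean, "sd": e.sd, "n": e.n}
                for k, e in self.entries.items()
            },
            "profiles": {
                side: {
                    m: {k: np.asarray(v).tolist() for k, v in d.items()}
                    for m, d in metrics.items()
                }
                for side, metrics in self.profiles.items()
            },
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "NormativeModel":
        try:
            doc = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                doc = json.load(fh)
        if doc.get("schema") != "hippoquant-normative/1":
            raise ValueError(f"unknown normative schema {doc.get('schema')!r}")
        entries = {k: NormativeEntry(**v) for k, v in doc["entries"].items()}
        profiles = {
            side: {m: {k: np.asarray(v) for k, v in d.items()} for m, d in metrics.items()}
            for side, metrics in doc.get("profiles", {}).items()
        }
        return cls(entries=entries, profiles=profiles, provenance=doc.get("provenance", {}))


@dataclass
class FlagSet:
    """Per-metric flags and the derived overall impression.

    flags: metric -> 'normal' | 'low' | 'high' (only metrics with a
    reference entry appear). overall: 'normal' | 'left_abnormal' |
    'right_abnormal' | 'bilateral_abnormal'.
    """

    flags: dict[str, str]
    overall: str


def reference_band(entry: NormativeEntry) -> tuple[float, float]:
    """(mean - 1.96 SD, mean + 1.96 SD)."""
    return entry.lo, entry.hi


def build_normative(
    cohort: list[tuple[GlobalMetrics, dict[str, HippocampusProfile] | None]],
    min_n: int = DEFAULT_MIN_N,
    seed: int | None = None,
) -> NormativeModel:
    """Per-metric mean/SD over the cohort; bands are mean +/- 1.96 SD.

    ``cohort`` holds (GlobalMetrics, profiles) pairs; profiles may be None
    throughout (ratio/global-only model) but must otherwise share one
    n_bins. Permutation-invariant in cohort order.
    """
    n = len(cohort)
    if n < min_n:
        raise ValueError(f"cohort of {n} below the minimum of {min_n}")

    entries = {}
    for name in GLOBAL_METRICS:
        # sorted before summation so the build is exactly permutation-invariant
        vals = np.sort(np.array([getattr(m, name) for m, _ in cohort], dtype=float))
        entries[name] = NormativeEntry(metric=name, mean=float(vals.mean()),
                                       sd=float(vals.std(ddof=1)), n=n)

    profiles: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    with_profiles = [p for _, p in cohort if p is not None]
    if with_profiles:
        if len(with_profiles) != n:
            raise ValueError("profiles must be given for all subjects or none")
        for side in ("left", "right"):
            n_bins = {p[side].n_bins for p in with_profiles}
            if len(n_bins) != 1:
                raise ValueError(f"inconsistent n_bins across cohort: {sorted(n_bins)}")
            positions = with_profiles[0][side].positions
            profiles[side] = {}
            for metric, attr in (("area_mm2", "area_mm2"), ("qt2_ms", "qt2_ms")):
                stack = np.sort(np.vstack([getattr(p[side], attr) for p in with_profiles]),
                                axis=0)  # NaN sort last; permutation invariance
                profiles[side][metric] = {
                    "positions": positions.copy(),
                    "mean": np.nanmean(stack, axis=0),
                    "sd": np.nanstd(stack, axis=0, ddof=1),
                }

    provenance = {
        "n": n,
        "seed": seed,
        "build_date": _dt.date.today().isoformat(),
        "source": "cohort",
    }
    return NormativeModel(entries=entries, profiles=profiles, provenance=provenance)


def default_ratio_model() -> NormativeModel:
    """The shipped published-range model: ratio metrics only, n = 111."""
    entries = {
        "lr_vol_ratio_pct": NormativeEntry.from_band("lr_vol_ratio_pct",
                                                     *PUBLISHED_VOL_RATIO_BAND, n=111),
        "lr_qt2_ratio_pct": NormativeEntry.from_band("lr_qt2_ratio_pct",
                                                     *PUBLISHED_QT2_RATIO_BAND, n=111),
    }
    return NormativeModel(
        entries=entries,
        provenance={"n": 111, "seed": None, "build_date": None,
                    "source": "published normative ranges (single-scanner 3T reference cohort)"},
    )


def _flag(value: float, entry: NormativeEntry) -> str:
    if value < entry.lo:
        return "low"
    if value > entry.hi:
        return "high"
    return "normal"


def flag_subject(
    metrics: GlobalMetrics,
    profiles: dict[str, HippocampusProfile] | None,
    model: NormativeModel,
) -> FlagSet:
    """Flag each referenced metric and derive the overall impression.

    Rules (machine advice, not a diagnosis):
    - a metric outside its band is 'low'/'high';
    - an abnormal L:R ratio names the implicated side (lower volume or
      higher qT2); if volume and qT2 ratios implicate opposite sides the
      impression is bilateral;
    - normal ratios with both sides' absolute volume low, or both sides'
      absolute qT2 high, give bilateral (the bilateral-disease pattern that
      leaves ratios near 100%);
    - otherwise normal.
    """
    model_bins = model.n_bins
    if profiles is not None and model_bins is not None:
        for side, prof in profiles.items():
            if prof.n_bins != model_bins:
                raise ValueError(f"profile n_bins {prof.n_bins} != model n_bins {model_bins}")

    flags = {
        name: _flag(getattr(metrics, name), entry)
        for name, entry in model.entries.items()
        if name in GLOBAL_METRICS
    }

    implicated: set[str] = set()
    vol_ratio_flag = flags.get("lr_vol_ratio_pct", "normal")
    qt2_ratio_flag = flags.get("lr_qt2_ratio_pct", "normal")
    if vol_ratio_flag != "normal":
        # low ratio -> left volume relatively small; high -> right small
        implicated.add("left" if vol_ratio_flag == "low" else "right")
    if qt2_ratio_flag != "normal":
        # high ratio -> left qT2 relatively high; low -> right high
        implicated.add("left" if qt2_ratio_flag == "high" else "right")

    if implicated == {"left"}:
        overall = "left_abnormal"
    elif implicated == {"right"}:
        overall = "right_abnormal"
    elif implicated == {"left", "right"}:
        overall = "bilateral_abnormal"
    else:
        both_vol_low = flags.get("vol_left") == "low" and flags.get("vol_right") == "low"
        both_qt2_high = flags.get("qt2_left") == "high" and flags.get("qt2_right") == "high"
        overall = "bilateral_abnormal" if (both_vol_low or both_qt2_high) else "normal"
    return FlagSet(flags=flags, overall=overall)
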