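"""Model configuration: typed parameter tables, JSON (de)serialization and
tabular output writing.

A full analysis is described by one :class:`ModelConfig` per country
perspective, holding the economic settings (discount rate, willingness to
pay, horizon, cycle length), the per-cycle cost table, the health-state
utilities and adverse-event disutilities, the two treatment arms (adverse
event probabilities, post-progression treatment mix, drug schedule with
cycle caps) and the four fitted survival distributions.  Every uncertain
scalar carries its base value, its low/high range and the distribution
family used for probabilistic draws (gamma for costs, beta for utilities
and probabilities).

Packaged configurations ``china`` and ``us`` encode the published input
tables for the pembrolizumab + gemcitabine/cisplatin vs chemotherapy
comparison in advanced biliary tract cancer; load them with
``load_config("china")``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .survfit import SurvDist

__all__ = [
    "Uncertain",
    "ParamRange",
    "EconSettings",
    "CostTable",
    "UtilityTable",
    "ArmProfile",
    "ModelConfig",
    "load_config",
    "write_results",
    "load_results",
    "FOLLOWUP_CATEGORIES",
]

FOLLOWUP_CATEGORIES = ("chemotherapy", "immunotherapy", "targeted", "other")


class Uncertain(BaseModel):
    """A scalar parameter with base value, range and draw distribution."""

    model_config = ConfigDict(frozen=True)

    base: float
    low: float | None = None
    high: float | None = None
    distribution: Literal["gamma", "beta"] | None = None

    @model_validator(mode="after")
    def _ordered(self) -> "Uncertain":
        if (self.low is None) != (self.high is None):
            raise ValueError("low and high must be given together")
        if self.low is not None and not (self.low <= self.base <= self.high):
            raise ValueError(
                f"range must satisfy low <= base <= high, got "
                f"{self.low} / {self.base} / {self.high}"
            )
        return self

    def __float__(self) -> float:
        return float(self.base)

    def range_or_default(self, frac: float = 0.25) -> tuple[float, float]:
        """The stated range, or +/-``frac`` of base when none is given."""
        if self.low is not None:
            return (self.low, self.high)
        lo, hi = self.base * (1 - frac), self.base * (1 + frac)
        return (min(lo, hi), max(lo, hi))


class ParamRange(BaseModel):
    """One named entry of the sensitivity-analysis parameter list."""

    model_config = ConfigDict(frozen=True)

    name: str
    base: float
    low: float
    high: float
    distribution_family: Literal["gamma", "beta"] | None = None

    @model_validator(mode="after")
    def _check(self) -> "ParamRange":
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: low <= base <= high violated")
        if self.distribution_family == "beta":
            lo, hi = sorted((abs(self.low), abs(self.high)))
            if not (0 <= lo and hi <= 1 and 0 < abs(self.base) < 1 or self.base == 0):
                if not (0 <= abs(self.base) <= 1 and hi <= 1):
                    raise ValueError(
                        f"{self.name}: beta requires magnitudes within [0, 1]"
                    )
        return self


class EconSettings(BaseModel):
    model_config = ConfigDict(frozen=True)

    country_label: str
    annual_discount_rate: float = Field(ge=0, lt=1)
    wtp_per_qaly: float = Field(gt=0)
    horizon_years: float = Field(gt=0)
    cycle_days: float = Field(gt=0)
    days_per_month: float = 30.4375

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / self.days_per_month

    @property
    def horizon_months(self) -> float:
        return self.horizon_years * 12.0


class CostTable(BaseModel):
    """Per-cycle drug costs, one-time adverse-event costs, imaging, and the
    composition of the post-progression regimens.

    Regimen per-cycle costs are sums of their member drugs' per-cycle costs
    (mFOLFOX = oxaliplatin + folinic acid + fluorouracil; "other" =
    irinotecan + capecitabine; immunotherapy = pembrolizumab; targeted =
    regorafenib)."""

    model_config = ConfigDict(frozen=True)

    per_cycle_drug_costs: dict[str, Uncertain]
    ae_costs: dict[str, Uncertain]
    imaging_cost_pfs: Uncertain
    followup_regimens: dict[str, list[str]]

    @model_validator(mode="after")
    def _check(self) -> "CostTable":
        for name, u in {**self.per_cycle_drug_costs, **self.ae_costs}.items():
            if u.base < 0:
                raise ValueError(f"cost {name} must be >= 0")
        if self.imaging_cost_pfs.base < 0:
            raise ValueError("imaging_cost_pfs must be >= 0")
        missing = set(FOLLOWUP_CATEGORIES) - set(self.followup_regimens)
        if missing:
            raise ValueError(f"followup_regimens missing categories {sorted(missing)}")
        for cat, drugs in self.followup_regimens.items():
            unknown = set(drugs) - set(self.per_cycle_drug_costs)
            if unknown:
                raise ValueError(
                    f"followup regimen {cat!r} references unknown drugs {sorted(unknown)}"
                )
        return self

    @property
    def followup_regimen_costs(self) -> dict[str, float]:
        return {
            cat: sum(self.per_cycle_drug_costs[d].base for d in drugs)
            for cat, drugs in self.followup_regimens.items()
        }


class UtilityTable(BaseModel):
    model_config = ConfigDict(frozen=True)

    u_pfs: Uncertain
    u_pd: Uncertain
    ae_disutilities: dict[str, Uncertain]

    @model_validator(mode="after")
    def _check(self) -> "UtilityTable":
        if not (0 <= self.u_pd.base <= self.u_pfs.base <= 1):
            raise ValueError(
                f"utilities must satisfy 0 <= u_pd <= u_pfs <= 1, got "
                f"u_pd={self.u_pd.base}, u_pfs={self.u_pfs.base}"
            )
        for name, u in self.ae_disutilities.items():
            if u.base > 0:
                raise ValueError(f"disutility {name} must be <= 0, got {u.base}")
        return self


class DrugLine(BaseModel):
    model_config = ConfigDict(frozen=True)

    drug: str
    max_cycles: int | None = None

    @model_validator(mode="after")
    def _check(self) -> "DrugLine":
        if self.max_cycles is not None and self.max_cycles < 1:
            raise ValueError(f"{self.drug}: max_cycles must be >= 1 where finite")
        return self


class ArmProfile(BaseModel):
    model_config = ConfigDict(frozen=True)

    arm_label: str
    ae_probabilities: dict[str, Uncertain]
    followup_mix: dict[str, Uncertain]
    drug_schedule: list[DrugLine]

    @model_validator(mode="after")
    def _check(self) -> "ArmProfile":
        for name, u in {**self.ae_probabilities, **self.followup_mix}.items():
            if not (0 <= u.base <= 1):
                raise ValueError(f"{self.arm_label}.{name}: probability outside [0,1]")
        missing = set(FOLLOWUP_CATEGORIES) - set(self.followup_mix)
        if missing:
            raise ValueError(f"{self.arm_label}: followup_mix missing {sorted(missing)}")
        total = sum(u.base for u in self.followup_mix.values())
        if abs(total - 1.0) > 0.02:
            raise ValueError(
                f"{self.arm_label}: followup_mix sums to {total:.3f}, expected ~1"
            )
        return self


class SurvivalPair(BaseModel):
    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    pfs: SurvDist
    os: SurvDist

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, v):
        if isinstance(v, dict):
            out = dict(v)
            for key in ("pfs", "os"):
                if isinstance(out.get(key), dict):
                    out[key] = SurvDist.from_dict(out[key])
            return out
        return v


class ModelConfig(BaseModel):
    """The complete model specification for one country perspective."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    settings: EconSettings
    costs: CostTable
    utilities: UtilityTable
    arms: dict[str, ArmProfile]
    survival: dict[str, SurvivalPair]

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if set(self.arms) != set(self.survival):
            raise ValueError("arms and survival must cover the same arm labels")
        for label, arm in self.arms.items():
            if arm.arm_label != label:
                raise ValueError(f"arm key {label!r} != arm_label {arm.arm_label!r}")
            for ae in arm.ae_probabilities:
                if ae not in self.costs.ae_costs:
                    raise ValueError(f"no cost entry for adverse event {ae!r}")
                if ae not in self.utilities.ae_disutilities:
                    raise ValueError(f"no disutility entry for adverse event {ae!r}")
            for line in arm.drug_schedule:
                if line.drug not in self.costs.per_cycle_drug_costs:
                    raise ValueError(f"no cost entry for scheduled drug {line.drug!r}")
        return self

    # -- flat parameter view (used by sensitivity analyses) ----------------

    def _uncertain_items(self):
        c = self.costs
        for d, u in sorted(c.per_cycle_drug_costs.items()):
            yield f"cost.drug.{d}", u
        for a, u in sorted(c.ae_costs.items()):
            yield f"cost.ae.{a}", u
        yield "cost.imaging_pfs", c.imaging_cost_pfs
        yield "utility.pfs", self.utilities.u_pfs
        yield "utility.pd", self.utilities.u_pd
        for a, u in sorted(self.utilities.ae_disutilities.items()):
            yield f"disutility.{a}", u
        for label, arm in sorted(self.arms.items()):
            for a, u in sorted(arm.ae_probabilities.items()):
                yield f"ae_prob.{label}.{a}", u
            for cat, u in sorted(arm.followup_mix.items()):
                yield f"followup_mix.{label}.{cat}", u

    def flat_params(self) -> dict[str, float]:
        """Base values of every model parameter keyed by flat name, plus the
        discount rate (``settings.annual_discount_rate``)."""
        out = {name: u.base for name, u in self._uncertain_items()}
        out["settings.annual_discount_rate"] = self.settings.annual_discount_rate
        return out

    def param_ranges(self, default_frac: float = 0.25) -> list[ParamRange]:
        """The sensitivity-analysis parameter list: every uncertain scalar
        with its stated range and draw distribution, plus the discount rate
        with a +/-25% range and no draw distribution (held fixed in PSA)."""
        out = []
        for name, u in self._uncertain_items():
            lo, hi = u.range_or_default(default_frac)
            out.append(
                ParamRange(
                    name=name, base=u.base, low=lo, high=hi,
                    distribution_family=u.distribution,
                )
            )
        r = self.settings.annual_discount_rate
        out.append(
            ParamRange(
                name="settings.annual_discount_rate",
                base=r, low=r * (1 - default_frac), high=r * (1 + default_frac),
                distribution_family=None,
            )
        )
        return out

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = self.model_dump(mode="json", exclude={"survival"})
        d["survival"] = {
            label: {"pfs": pair.pfs.to_dict(), "os": pair.os.to_dict()}
            for label, pair in self.survival.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls.model_validate(d)


_PACKAGED = {"china": "china.json", "us": "us.json"}


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration.

    ``path`` is either a JSON file path or one of the packaged country
    labels ``"china"`` / ``"us"``.
    """
    key = str(path).lower()
    if key in _PACKAGED:
        text = (resources.files("pembrocea") / "data" / _PACKAGED[key]).read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"no such config file: {p}")
        text = p.read_text()
    return ModelConfig.from_dict(json.loads(text))


def save_config(config: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True) + "\n")


# -- output writing ---------------------------------------------------------

_CSV_COLUMNS = {
    "trace": ["cycle", "t_mid_months", "p_pfs", "p_pd", "p_dead", "disc_factor"],
    "tornado": ["param", "low_icer", "high_icer", "width"],
    "ceac": ["wtp", "probability"],
}


def _fmt_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.6f}")
    return out


def write_results(results: Mapping[str, object], out_dir: str | Path) -> list[Path]:
    """Write analysis artifacts as deterministic CSV/JSON files.

    ``results`` maps artifact names to objects: ``"results"`` (a CEAResult,
    written as results.json), ``"trace"``/``"tornado"``/``"psa_samples"``/
    ``"ceac"`` (DataFrames, written as <name>.csv).  Floats are written at
    fixed 6-decimal precision so re-running with the same seed is
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        if hasattr(obj, "to_dict") and not isinstance(obj, pd.DataFrame):
            path = out / f"{name}.json"
            path.write_text(json.dumps(obj.to_dict(), indent=1, sort_keys=True) + "\n")
        else:
            df = obj if isinstance(obj, pd.DataFrame) else pd.DataFrame(obj)
            cols = _CSV_COLUMNS.get(name)
            if cols is not None:
                df = df[cols]
            path = out / f"{name}.csv"
            _fmt_frame(df).to_csv(path, index=False)
        written.append(path)
    return written


def load_results(path: str | Path) -> dict:
    """Read back a results.json written by :func:`write_results`."""
    return json.loads(Path(path).read_text())
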