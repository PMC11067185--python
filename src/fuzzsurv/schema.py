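"""Cohort schema: the ordered categorical variables of a clinicopathologic table.

The default schema describes the 15 predictor variables recorded for each
oral squamous cell carcinoma (OSCC) patient — demographics, tumor site, TNM
staging components, adverse pathologic features, primary treatment, and
post-operative events — plus the two outcome columns ``survival_months`` and
``survival_class``. Alternate cohorts can declare their own schema as a JSON
document with the same shape as ``data/schema.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

SURVIVAL_MONTHS = "survival_months"
SURVIVAL_CLASS = "survival_class"
N_CLASSES = 6

#: sentinels accepted for a missing value in CSV cells
MISSING_SENTINELS = ("", "NA")


@dataclass(frozen=True)
class Variable:
    """One categorical predictor: a name and its ordered set of levels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(set(self.levels)):
            raise ValueError(f"duplicate levels in variable {self.name!r}")


@dataclass(frozen=True)
class CohortSchema:
    """Ordered predictor variables shared by every record of a cohort."""

    variables: tuple[Variable, ...]
    version: int = 1
    name: str = "custom"

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def columns(self) -> list[str]:
        """Canonical CSV column order: predictors then the two outcome columns."""
        return self.variable_names + [SURVIVAL_MONTHS, SURVIVAL_CLASS]

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def levels(self, name: str) -> tuple[str, ...]:
        return self.variable(name).levels

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSchema":
        return cls(
            variables=tuple(Variable(v["name"], tuple(v["levels"])) for v in d["variables"]),
            version=int(d.get("version", 1)),
            name=str(d.get("name", "custom")),
        )

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "name": self.name,
            "variables": [{"name": v.name, "levels": list(v.levels)} for v in self.variables],
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def _load_packaged(name: str) -> dict:
    with resources.files("fuzzsurv.data").joinpath(name).open(encoding="utf-8") as fh:
        return json.load(fh)


def default_schema() -> CohortSchema:
    """The packaged 15-variable OSCC schema."""
    return CohortSchema.from_dict(_load_packaged("schema.json"))


def table1_counts() -> dict:
    """The published per-variable level counts of the 581-patient cohort table.

    Returns a dict with keys ``n`` (cohort size) and ``counts`` (variable ->
    level -> count, with survival classes keyed "0".."5").
    """
    return _load_packaged("table1.json")
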