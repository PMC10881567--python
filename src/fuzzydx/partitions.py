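"""Partition registry: named linguistic variables with JSON round-tripping.

The default config ships one fuzzy partition per clinically discriminative
feature (cognitive scores, FDG, MRI volumetrics, CSF markers, the two
severity bridge variables, and the diagnosis output variable ``DR``).  All
default partitions are Ruspini partitions — membership degrees sum to one
everywhere in the domain — built from shoulder trapezoids at the domain
edges with triangles between them.  Breakpoints are data, not code: users
override any variable by supplying their own JSON file.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Iterator, Mapping

from .errors import UnknownVariable
from .fuzzy import LinguisticVariable, MembershipFunction

_DEFAULT_RESOURCE = "partitions.json"


class PartitionRegistry:
    """Case-insensitive, alias-aware lookup of linguistic variables."""

    def __init__(self, variables: Mapping[str, LinguisticVariable] | None = None):
        self._vars: dict[str, LinguisticVariable] = {}
        self._index: dict[str, str] = {}  # lowercased name/alias -> canonical
        for var in (variables or {}).values():
            self.add(var)

    def add(self, var: LinguisticVariable) -> None:
        if var.name in self._vars:
            raise ValueError(f"variable {var.name!r} already registered")
        for key in (var.name, *var.aliases):
            low = key.lower()
            if low in self._index and self._index[low] != var.name:
                raise ValueError(f"name clash on {key!r}")
            self._index[low] = var.name
        self._vars[var.name] = var

    def resolve(self, name: str) -> str | None:
        """Canonical variable name for ``name`` (case/alias tolerant), or None."""
        return self._index.get(name.lower())

    def get(self, name: str) -> LinguisticVariable:
        canonical = self.resolve(name)
        if canonical is None:
            raise UnknownVariable(f"no partition registered for variable {name!r}")
        return self._vars[canonical]

    def __contains__(self, name: str) -> bool:
        return self.resolve(name) is not None

    def __iter__(self) -> Iterator[LinguisticVariable]:
        return iter(self._vars.values())

    def __len__(self) -> int:
        return len(self._vars)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._vars)

    # ---- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        payload: dict = {"version": 1, "variables": {}}
        for var in self:
            payload["variables"][var.name] = {
                "domain": list(var.domain),
                "aliases": list(var.aliases),
                "terms": [
                    {
                        "label": label,
                        "shape": var.sets[label].shape,
                        "breakpoints": list(var.sets[label].breakpoints),
                    }
                    for label in var.labels
                ],
            }
        return payload

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PartitionRegistry":
        if "variables" not in payload:
            raise ValueError("partition config must contain a 'variables' mapping")
        registry = cls()
        for name, spec in payload["variables"].items():
            for key in ("domain", "terms"):
                if key not in spec:
                    raise ValueError(f"partition {name!r} missing {key!r}")
            labels = []
            sets = {}
            for term in spec["terms"]:
                labels.append(term["label"])
                sets[term["label"]] = MembershipFunction(
                    term["shape"], tuple(term["breakpoints"])
                )
            registry.add(
                LinguisticVariable(
                    name=name,
                    domain=tuple(spec["domain"]),
                    labels=tuple(labels),
                    sets=sets,
                    aliases=tuple(spec.get("aliases", ())),
                )
            )
        return registry

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load_json(cls, path) -> "PartitionRegistry":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "PartitionRegistry":
        """The versioned default partitions shipped with the package."""
        text = resources.files("fuzzydx.data").joinpath(_DEFAULT_RESOURCE).read_text("utf-8")
        return cls.from_dict(json.loads(text))


def default_output_variable(registry: PartitionRegistry | None = None) -> LinguisticVariable:
    """The diagnosis output variable ``DR`` from a registry (default: shipped)."""
    registry = registry or PartitionRegistry.default()
    return registry.get("DR")
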