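"""Regulons and interactomes.

A *regulon* is the set of transcriptional targets of a regulatory protein,
each target carrying a regulation *mode* in [-1, +1] (sign: activation vs.
repression; magnitude: confidence in that sign) and an interaction
*likelihood* in (0, 1] (confidence that the target belongs to the regulon
at all).  An *interactome* is a named, context-specific collection of
regulons, one per regulator — typically reverse engineered from a cohort
of expression profiles for one tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np


class ValidationError(ValueError):
    """Raised when a regulon/interactome violates its invariants."""


@dataclass
class Regulon:
    """One regulator's signed, weighted target set.

    Parameters
    ----------
    regulator : str
        Gene identifier of the regulatory protein. Identifiers are opaque,
        case-sensitive strings; no symbol mapping is performed.
    targets : ndarray of str
        Unique target gene identifiers (at least one).
    mode : ndarray of float
        Per-target regulation mode in [-1, +1].
    likelihood : ndarray of float
        Per-target interaction confidence in (0, 1].
    """

    regulator: str
    targets: np.ndarray
    mode: np.ndarray
    likelihood: np.ndarray

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=object)
        self.mode = np.asarray(self.mode, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.targets.size == 0:
            raise ValidationError(f"regulon {self.regulator!r}: needs at least 1 target")
        if len({*self.targets}) != self.targets.size:
            raise ValidationError(f"regulon {self.regulator!r}: duplicate targets")
        if not (self.mode.size == self.likelihood.size == self.targets.size):
            raise ValidationError(
                f"regulon {self.regulator!r}: targets/mode/likelihood length mismatch"
            )
        if not np.all(np.isfinite(self.mode)) or np.any(np.abs(self.mode) > 1):
            raise ValidationError(f"regulon {self.regulator!r}: mode outside [-1, 1]")
        if (
            not np.all(np.isfinite(self.likelihood))
            or np.any(self.likelihood <= 0)
            or np.any(self.likelihood > 1)
        ):
            raise ValidationError(f"regulon {self.regulator!r}: likelihood outside (0, 1]")

    @property
    def size(self) -> int:
        return int(self.targets.size)

    @property
    def has_self_loop(self) -> bool:
        """Regulator appearing among its own targets (permitted but flagged)."""
        return self.regulator in set(self.targets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Regulon):
            return NotImplemented
        if self.regulator != other.regulator or self.size != other.size:
            return False
        order_a = np.argsort(self.targets.astype(str))
        order_b = np.argsort(other.targets.astype(str))
        return (
            np.array_equal(self.targets[order_a], other.targets[order_b])
            and np.allclose(self.mode[order_a], other.mode[order_b])
            and np.allclose(self.likelihood[order_a], other.likelihood[order_b])
        )


@dataclass
class Interactome:
    """Named collection of regulons for one context/tissue."""

    name: str
    regulons: dict[str, Regulon] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for key, reg in self.regulons.items():
            if key != reg.regulator:
                raise ValidationError(
                    f"interactome {self.name!r}: key {key!r} != regulator {reg.regulator!r}"
                )

    def __len__(self) -> int:
        return len(self.regulons)

    def __iter__(self) -> Iterator[Regulon]:
        return iter(self.regulons.values())

    def __contains__(self, regulator: str) -> bool:
        return regulator in self.regulons

    def __getitem__(self, regulator: str) -> Regulon:
        return self.regulons[regulator]

    @property
    def regulators(self) -> list[str]:
        return list(self.regulons)

    def subset(self, regulators: Mapping[str, None] | list[str]) -> "Interactome":
        return Interactome(
            name=self.name,
            regulons={r: self.regulons[r] for r in regulators if r in self.regulons},
            provenance=self.provenance,
        )
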