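"""Shared result containers."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class DiffusionEstimate:
    """A diffusion coefficient with uncertainty and provenance.

    ``value``/``uncertainty`` in Å²/ns (translational) or 1/ns (rotational).
    ``corrections`` records which post-hoc corrections have been applied so
    that idempotent-guarded steps (finite-size, isotope, crowding) are not
    applied twice.
    """

    value: float
    uncertainty: float = 0.0
    r_squared: float | None = None
    method: str = ""
    corrections: set[str] = field(default_factory=set)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")

    def with_correction(self, name: str, value: float) -> "DiffusionEstimate":
        if name in self.corrections:
            raise ValueError(f"correction {name!r} already applied")
        return DiffusionEstimate(
            value=value,
            uncertainty=self.uncertainty * (value / self.value if self.value else 1.0),
            r_squared=self.r_squared,
            method=self.method,
            corrections=self.corrections | {name},
            flags=set(self.flags),
        )
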