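"""Propagation settings."""
from __future__ import annotations

from dataclasses import asdict, dataclass

__all__ = ["PropagationSettings"]


@dataclass
class PropagationSettings:
    """Surface-hopping propagation parameters.

    ``dt_el`` must divide ``dt_nuc`` and ``t_final`` must be a multiple of
    ``dt_nuc``.  ``decoherence_c`` is the energy-based decoherence constant
    in hartree (0.1 is the standard choice).
    """

    dt_nuc: float = 0.5  # fs
    dt_el: float = 0.02  # fs
    t_final: float = 1000.0  # fs
    decoherence: bool = True
    decoherence_c: float = 0.1  # hartree
    frustrated_policy: str = "keep"  # or "reverse"
    freeze_nuclei: bool = False
    hopping: bool = True
    seed: int = 0
    max_drift_ev: float = 0.05  # allowed |dE_total| over any 100-step window

    def __post_init__(self) -> None:
        if self.dt_nuc <= 0 or self.dt_el <= 0 or self.t_final <= 0:
            raise ValueError("time steps and final time must be positive")
        ratio = self.dt_nuc / self.dt_el
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dt_el must divide dt_nuc")
        steps = self.t_final / self.dt_nuc
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("t_final must be a multiple of dt_nuc")
        if self.frustrated_policy not in ("keep", "reverse"):
            raise ValueError("frustrated_policy must be 'keep' or 'reverse'")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_final / self.dt_nuc))

    @property
    def n_substeps(self) -> int:
        return int(round(self.dt_nuc / self.dt_el))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PropagationSettings":
        return cls(**d)
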