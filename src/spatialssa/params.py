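"""Kinetic rate constants for the gene-regulation models.

All propensities are mass-action.  The bimolecular binding step is scaled by
the system size ``omega``: its propensity is ``(kf / omega) * D * P``.  In the
compartment-based (spatial) simulations ``omega = 1`` represents the volume of
a single lattice compartment; the matched well-mixed simulation uses
``omega = K`` (the number of compartments) so that both describe the same
physical volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["RateParameters"]

_KD_RTOL = 1e-12


@dataclass(frozen=True)
class RateParameters:
    """Rate constants of the repressor-binding gene-expression model.

    Parameters
    ----------
    kf : float
        Binding rate constant.  The binding propensity is ``kf / omega * D * P``,
        so ``kf`` itself carries units of 1/s at ``omega = 1``.
    kb : float
        Unbinding rate of the DNA-repressor complex (1/s).
    kp : float
        Transcription rate per free binding site (1/s).
    kd : float
        mRNA degradation rate (1/s).
    delta : float
        Diffusion coefficient of the free repressor protein (um^2/s).
    omega : float
        System size (volume in units of one lattice compartment).
    Kd : float, optional
        Dissociation constant ``kb / (kf / omega)``.  Derived when omitted;
        if given it must agree with the derived value to relative 1e-12.
    """

    kf: float
    kb: float
    kp: float = 0.0
    kd: float = 0.0
    delta: float = 0.0
    omega: float = 1.0
    Kd: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("kf", "kb", "kp", "kd", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name!r} must be >= 0")
        if self.omega <= 0:
            raise ValueError("system size omega must be > 0")
        if self.kf > 0:
            derived = self.kb / (self.kf / self.omega)
        else:
            derived = float("inf")
        if self.Kd is None:
            object.__setattr__(self, "Kd", derived)
        elif abs(self.Kd - derived) > _KD_RTOL * max(abs(derived), 1.0):
            raise ValueError(
                f"Kd={self.Kd} inconsistent with kb/(kf/omega)={derived}"
            )

    @property
    def kf_per_omega(self) -> float:
        """Per-volume binding rate ``kf / omega`` used in propensities."""
        return self.kf / self.omega

    def with_omega(self, omega: float) -> "RateParameters":
        """Same rate constants in a system of a different size."""
        return RateParameters(
            kf=self.kf, kb=self.kb, kp=self.kp, kd=self.kd,
            delta=self.delta, omega=omega,
        )
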