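"""Reference parameter bundles for the canonical operating points.

Each preset collects the population constants, synaptic weights, drive
protocol and (where relevant) cross-circuit coupling of one of the
standard study conditions: the PING circuit (rhythm carried by the
E->I->E loop, J_ii = 0), the ING circuit (rhythm carried by the I->I
loop, J_ie = 0, drive on both populations), and the delay-coupled pairs
built from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import PresetNotFoundError
from .params import (
    CrossCoupling,
    DriveProtocol,
    PopulationParams,
    Pulse,
    SynapticCouplings,
)

__all__ = ["ConfigBundle", "figure_preset", "PRESET_NAMES"]


@dataclass(frozen=True)
class ConfigBundle:
    """Complete, validated description of one simulation / analysis setup."""

    name: str
    e_params: PopulationParams
    i_params: PopulationParams
    couplings: SynapticCouplings
    drive_e: DriveProtocol
    drive_i: DriveProtocol
    cross_coupling: CrossCoupling | None = None
    pulse: Pulse | None = None
    duration: float = 300.0
    step: float = 0.01
    seed: int = 0

    @property
    def drive_values(self) -> tuple[float, float]:
        """Constant drives at t = 0 (the full protocols may vary in time)."""
        return (self.drive_e.value_at(0.0), self.drive_i.value_at(0.0))


_POP = PopulationParams(tau=10.0, eta_bar=-5.0, delta=1.0, size=5000,
                        v_th=500.0, v_reset=-500.0)

# step-drive protocol spanning quiescent and oscillatory regimes; the
# stimulus trace of the mean-field validation figure is qualitative, so
# these levels are the package's fixed choice (see docs/methods.md)
_FIG1_DRIVE = DriveProtocol(((0.0, 1.5), (75.0, 6.0), (150.0, 10.0), (225.0, 3.0)))

_PING_J = SynapticCouplings(j_ee=0.0, j_ei=15.0, j_ie=15.0, j_ii=0.0, tau_s=1.0)
_ING_J = SynapticCouplings(j_ee=0.0, j_ei=10.0, j_ie=0.0, j_ii=15.0, tau_s=1.0)


def _build_presets() -> dict[str, ConfigBundle]:
    ping = ConfigBundle(
        name="fig2_ping",
        e_params=_POP,
        i_params=_POP,
        couplings=_PING_J,
        drive_e=DriveProtocol.constant(10.0),
        drive_i=DriveProtocol.constant(0.0),
    )
    ing = ConfigBundle(
        name="fig3_ing",
        e_params=_POP,
        i_params=_POP,
        couplings=_ING_J,
        drive_e=DriveProtocol.constant(25.0),
        drive_i=DriveProtocol.constant(25.0),
    )
    presets = {
        "fig1": ConfigBundle(
            name="fig1",
            e_params=_POP,
            i_params=_POP,
            couplings=SynapticCouplings(j_ee=0.0, j_ei=15.0, j_ie=15.0, j_ii=10.0,
                                        tau_s=1.0),
            drive_e=_FIG1_DRIVE,
            drive_i=DriveProtocol.constant(0.0),
            duration=300.0,
        ),
        "fig2_ping": ping,
        "fig3_ing": ing,
        "fig5_coupled": replace(
            ping, name="fig5_coupled",
            cross_coupling=CrossCoupling(g_ee=0.1, g_ie=0.5, delay=0.0),
        ),
        "fig6_scan": replace(
            ping, name="fig6_scan",
            cross_coupling=CrossCoupling(g_ee=0.1, g_ie=0.5, delay=6.0),
        ),
        "fig7_ing_coupled": replace(
            ing, name="fig7_ing_coupled",
            cross_coupling=CrossCoupling(g_ee=0.0, g_ie=0.3, delay=0.0),
        ),
        "fig9_global": replace(
            ping, name="fig9_global",
            cross_coupling=CrossCoupling(g_ee=0.1, g_ie=0.5, delay=6.0),
            pulse=Pulse(amplitude=1.0, duration=0.1, population="e"),
        ),
    }
    return presets


_PRESETS = _build_presets()
PRESET_NAMES = tuple(sorted(_PRESETS))


def figure_preset(name: str) -> ConfigBundle:
    """Return the named reference parameter bundle.

    Valid names: fig1, fig2_ping, fig3_ing, fig5_coupled, fig6_scan,
    fig7_ing_coupled, fig9_global.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise PresetNotFoundError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None
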