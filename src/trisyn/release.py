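"""Three-pool synaptic resource dynamics and spike-triggered release.

The presynaptic terminal carries fractions of recovered (x), active (y) and
inactive (z) vesicle resources with x + y + z = 1.  Between spikes the pools
relax (y -> z with time constant tau_i, z -> x with tau_r); at each spike a
fraction U of the recovered pool becomes active, and the released fraction
U x sets the amount of transmitter injected into the cleft:

* Glu:  glu_scale * (U x) mM added instantaneously (impulse mode), or a
  continuous source glu_scale * y(t) mM/s (continuous mode);
* K+:   a fixed k_release mM per spike.

Both injections are external to the astrocytic flux bookkeeping and are
tracked in the simulator's injection ledger.
"""

from __future__ import annotations

from dataclasses import dataclass

from numba import njit

__all__ = [
    "ResourceState",
    "resource_derivatives",
    "apply_spike",
    "release_into_synapse",
]


@dataclass
class ResourceState:
    """Resource fractions; invariant x + y + z = 1."""

    x: float = 1.0
    y: float = 0.0
    z: float = 0.0


@njit(cache=True)
def resource_derivatives(x, y, z, tau_r, tau_i):
    """Continuous (between-spike) part: (dx/dt, dy/dt, dz/dt); sums to zero."""
    dx = z / tau_r
    dy = -y / tau_i
    dz = y / tau_i - z / tau_r
    return dx, dy, dz


@njit(cache=True)
def apply_spike(x, y, z, u):
    """Instantaneous spike update: a fraction u of x is released into y.

    Returns (x', y', z', released_fraction) with released_fraction = u*x.
    """
    released = u * x
    return x - released, y + released, z, released


@njit(cache=True)
def release_into_synapse(released_fraction, glu_scale, k_release):
    """Per-spike transmitter injection (dGlu_syn, dK_syn) in mM."""
    if released_fraction <= 0.0:
        return 0.0, 0.0
    return glu_scale * released_fraction, k_release
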