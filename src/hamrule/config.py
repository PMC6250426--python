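"""Central numerical tolerances.

All tolerance defaults used across the package live in one frozen object so
that a single override propagates consistently.
"""
from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class Tolerances:
    """Numerical tolerances used by the structure and selection engines.

    Attributes
    ----------
    structure : float
        Allowed violation of the simplex (sum to one) and mean-frequency
        (sum of (i/n) f_i = p) constraints for analytic structure families.
    profile_analytic : float
        Normalisation slack for endpoint profiles obtained in closed form.
    profile_numeric : float
        Normalisation slack for endpoint profiles obtained by numerical
        one-sided limits.
    limit_convergence : float
        Convergence threshold for successive Richardson extrapolants in the
        numerical endpoint-limit path.
    root : float
        |S| below which a refined interior frequency counts as a root of the
        selection differential.
    equality : float
        Slack for "holds with equality" decisions (equal gains, neutral
        invasion, degenerate dynamics).
    violation : float
        |rb - c| above which inclusive fitness at an equilibrium counts as a
        genuine disagreement with the direction of selection.
    """

    structure: float = 1e-9
    profile_analytic: float = 1e-12
    profile_numeric: float = 1e-6
    limit_convergence: float = 1e-7
    root: float = 1e-10
    equality: float = 1e-9
    violation: float = 1e-8

    def with_(self, **kwargs) -> "Tolerances":
        """Return a copy with selected tolerances replaced."""
        return replace(self, **kwargs)


DEFAULT_TOL = Tolerances()
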