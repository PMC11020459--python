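"""Link functions mapping area proportions to the linking-model scale.

The three area-level models differ only in how the true proportion
``theta`` enters the linking regression: directly (identity), through
``log(theta)`` or through ``logit(theta)``.  The logit link is the only
one whose inverse is guaranteed to land in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit, logit as _logit

LINK_NAMES = ("identity", "log", "logit")


@dataclass(frozen=True)
class LinkSpec:
    """A named link with forward and inverse transforms.

    ``transform`` maps the proportion scale to the link (mu) scale,
    ``inverse`` maps back.  ``domain`` is the open interval of proportion
    values on which ``transform`` is finite.
    """

    name: str
    transform: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    inverse: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    domain: tuple[float, float] = (-np.inf, np.inf)

    def in_domain(self, theta: np.ndarray) -> np.ndarray:
        lo, hi = self.domain
        theta = np.asarray(theta, dtype=float)
        return (theta > lo) & (theta < hi)


_LINKS = {
    "identity": LinkSpec("identity", lambda t: np.asarray(t, dtype=float),
                         lambda m: np.asarray(m, dtype=float)),
    "log": LinkSpec("log", np.log, np.exp, domain=(0.0, np.inf)),
    "logit": LinkSpec("logit", _logit, expit, domain=(0.0, 1.0)),
}


def get_link(name: str | LinkSpec) -> LinkSpec:
    """Resolve a link by name ("identity", "log" or "logit")."""
    if isinstance(name, LinkSpec):
        return name
    try:
        return _LINKS[name]
    except KeyError:
        raise ValueError(
            f"unknown link {name!r}; expected one of {LINK_NAMES}"
        ) from None
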