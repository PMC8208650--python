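"""Builders for the stellate/interneuron network topologies.

Four wiring patterns are provided:

* a 2+2 **motif** (two stellate cells, two mutually inhibitory interneurons);
* a **ring** of 40 stellate cells and 40 interneurons, where each interneuron
  inhibits the 5 adjacent stellate cells with a Gaussian weight profile and
  each stellate cell excites 6 randomly chosen interneurons;
* an **asymmetric ring** in which the random feedback excitation is replaced
  by a local Gaussian profile shifted off-center;
* a **dual ring** of two 40-interneuron groups inhibiting a common pool of
  stellate cells (competing input streams).

In every topology the interneurons are all-to-all inhibitory (no autapses).
Weight matrices store absolute conductances in mS/cm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "build_motif",
    "build_ring",
    "build_asymmetric_ring",
    "build_dual_ring",
]

#: default maximal conductances (mS/cm²)
G_II = 1.0   # interneuron → interneuron inhibition
G_IE = 0.6   # interneuron → stellate inhibition
G_EI = 0.03  # stellate → interneuron excitation

#: default constant drives (μA/cm²)
IEXT_STELLATE = -2.7
IEXT_INTERNEURON = 0.2


@dataclass
class NetworkSpec:
    """Populations, typed synaptic weight blocks and constant drives.

    Weight blocks (absolute conductance, mS/cm²):

    * ``w_ie`` — shape (n_interneuron, n_stellate): inhibition onto stellates
    * ``w_ei`` — shape (n_stellate, n_interneuron): excitation onto interneurons
    * ``w_ii`` — shape (n_interneuron, n_interneuron): mutual inhibition
    """

    n_stellate: int
    n_interneuron: int
    w_ie: np.ndarray
    w_ei: np.ndarray
    w_ii: np.ndarray
    iext_s: np.ndarray
    iext_i: np.ndarray
    groups: np.ndarray | None = None  # interneuron group labels (dual ring)
    name: str = "network"

    def validate(self) -> None:
        ns, ni = self.n_stellate, self.n_interneuron
        if self.w_ie.shape != (ni, ns):
            raise ValueError("w_ie must be (n_interneuron, n_stellate)")
        if self.w_ei.shape != (ns, ni):
            raise ValueError("w_ei must be (n_stellate, n_interneuron)")
        if self.w_ii.shape != (ni, ni):
            raise ValueError("w_ii must be (n_interneuron, n_interneuron)")
        for name in ("w_ie", "w_ei", "w_ii"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"{name} has negative weights")
        if np.diag(self.w_ii).any():
            raise ValueError("autapses are not allowed in w_ii")
        if self.iext_s.shape != (ns,) or self.iext_i.shape != (ni,):
            raise ValueError("constant drive vectors have wrong shape")

    def to_edge_list(self) -> str:
        """Plain-text edge list: block, pre index, post index, weight."""
        lines = ["# block\tpre\tpost\tweight"]
        for block, w in (("ie", self.w_ie), ("ei", self.w_ei), ("ii", self.w_ii)):
            pre, post = np.nonzero(w)
            for p, q in zip(pre, post):
                lines.append(f"{block}\t{p}\t{q}\t{w[p, q]:.6g}")
        return "\n".join(lines) + "\n"


def _all_to_all(n: int, g: float) -> np.ndarray:
    w = np.full((n, n), g)
    np.fill_diagonal(w, 0.0)
    return w


def build_motif(
    include_feedback_excitation: bool = True,
    g_ii: float = G_II,
    g_ie: float = G_IE,
    g_ei: float = G_EI,
    iext_s: float = IEXT_STELLATE,
    iext_i: float = IEXT_INTERNEURON,
) -> NetworkSpec:
    """2 stellate + 2 interneuron motif.

    Interneuron j inhibits its partner stellate cell j and the other
    interneuron; stellate cell j excites the *opposite* interneuron (1−j)
    when feedback excitation is enabled, which closes the loop that makes
    the motif an autonomous oscillator.
    """
    w_ie = g_ie * np.eye(2)
    w_ii = _all_to_all(2, g_ii)
    w_ei = np.zeros((2, 2))
    if include_feedback_excitation:
        w_ei[0, 1] = g_ei
        w_ei[1, 0] = g_ei
    spec = NetworkSpec(
        n_stellate=2,
        n_interneuron=2,
        w_ie=w_ie,
        w_ei=w_ei,
        w_ii=w_ii,
        iext_s=np.full(2, float(iext_s)),
        iext_i=np.full(2, float(iext_i)),
        name="motif",
    )
    spec.validate()
    return spec


def _gaussian_inhibition(
    n_i: int, n_s: int, fanout: int, sigma: float, g_ie: float
) -> np.ndarray:
    """Interneuron i → the ``fanout`` stellate cells centered on index i.

    Weights Gaussian in ring distance, peak-normalized so the central weight
    equals ``g_ie``.
    """
    if fanout > n_s:
        raise ValueError("inhibitory fan-out exceeds stellate population")
    half = fanout // 2
    w = np.zeros((n_i, n_s))
    offsets = np.arange(-half, fanout - half)
    for i in range(n_i):
        for d in offsets:
            w[i, (i + d) % n_s] = g_ie * np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return w


def build_ring(
    n_stellate: int = 40,
    n_interneuron: int = 40,
    inhib_fanout: int = 5,
    excit_fanout: int = 6,
    sigma: float = 1.25,
    g_ii: float = G_II,
    g_ie: float = G_IE,
    g_ei: float = G_EI,
    iext_s: float = IEXT_STELLATE,
    iext_i: float = IEXT_INTERNEURON,
    include_feedback_excitation: bool = True,
    seed: int = 0,
) -> NetworkSpec:
    """Ring of stellate cells inhibited by a matching interneuron ring.

    Each interneuron inhibits ``inhib_fanout`` adjacent stellate cells
    (Gaussian profile); each stellate cell excites ``excit_fanout``
    interneurons drawn uniformly without replacement under ``seed``.
    """
    if excit_fanout > n_interneuron:
        raise ValueError("excitatory fan-out exceeds interneuron population")
    w_ie = _gaussian_inhibition(n_interneuron, n_stellate, inhib_fanout, sigma, g_ie)
    w_ei = np.zeros((n_stellate, n_interneuron))
    if include_feedback_excitation:
        rng = np.random.default_rng(seed)
        for j in range(n_stellate):
            targets = rng.choice(n_interneuron, size=excit_fanout, replace=False)
            w_ei[j, targets] = g_ei
    spec = NetworkSpec(
        n_stellate=n_stellate,
        n_interneuron=n_interneuron,
        w_ie=w_ie,
        w_ei=w_ei,
        w_ii=_all_to_all(n_interneuron, g_ii),
        iext_s=np.full(n_stellate, float(iext_s)),
        iext_i=np.full(n_interneuron, float(iext_i)),
        name="ring",
    )
    spec.validate()
    return spec


def build_asymmetric_ring(
    offset: int = 2,
    sigma_e: float = 1.5,
    excit_fanout: int = 5,
    n_stellate: int = 40,
    n_interneuron: int = 40,
    inhib_fanout: int = 5,
    sigma: float = 1.25,
    g_ii: float = G_II,
    g_ie: float = G_IE,
    g_ei: float = G_EI,
    iext_s: float = IEXT_STELLATE,
    iext_i: float = IEXT_INTERNEURON,
) -> NetworkSpec:
    """Ring with local, asymmetrically shifted feedback excitation.

    Stellate j excites a Gaussian neighborhood of interneurons centered at
    j + offset; each cell's outgoing excitation is normalized to the same
    total (4·g_ei).  Concentrating the full random-regime aggregate (6·g_ei)
    on a handful of neighbors makes single feedback synapses strong enough
    to override the theta gate, so the local profile carries two thirds of
    that aggregate.
    """
    if abs(offset) >= n_interneuron // 2:
        raise ValueError("offset must be smaller than half the ring")
    w_ie = _gaussian_inhibition(n_interneuron, n_stellate, inhib_fanout, sigma, g_ie)
    half = excit_fanout // 2
    offsets = np.arange(-half, excit_fanout - half)
    profile = np.exp(-(offsets ** 2) / (2.0 * sigma_e ** 2))
    profile *= 4.0 * g_ei / profile.sum()
    w_ei = np.zeros((n_stellate, n_interneuron))
    for j in range(n_stellate):
        for d, g in zip(offsets, profile):
            w_ei[j, (j + offset + d) % n_interneuron] = g
    spec = NetworkSpec(
        n_stellate=n_stellate,
        n_interneuron=n_interneuron,
        w_ie=w_ie,
        w_ei=w_ei,
        w_ii=_all_to_all(n_interneuron, g_ii),
        iext_s=np.full(n_stellate, float(iext_s)),
        iext_i=np.full(n_interneuron, float(iext_i)),
        name="asymmetric_ring",
    )
    spec.validate()
    return spec


def build_dual_ring(
    n_per_group: int = 40,
    n_stellate: int = 40,
    inhib_fanout: int = 5,
    excit_fanout: int = 6,
    sigma: float = 1.25,
    g_ii: float = G_II,
    g_ie: float = G_IE,
    g_ei: float = G_EI,
    iext_s: float = IEXT_STELLATE,
    iext_i: float = IEXT_INTERNEURON,
    include_feedback_excitation: bool = True,
    seed: int = 0,
) -> NetworkSpec:
    """Two interneuron rings inhibiting one common stellate pool.

    Both groups wire onto the stellate ring exactly as in :func:`build_ring`;
    all 2·n_per_group interneurons are mutually inhibitory, so the two input
    streams compete for the same pool.
    """
    n_i = 2 * n_per_group
    w_ie = np.zeros((n_i, n_stellate))
    block = _gaussian_inhibition(n_per_group, n_stellate, inhib_fanout, sigma, g_ie)
    w_ie[:n_per_group] = block
    w_ie[n_per_group:] = block
    w_ei = np.zeros((n_stellate, n_i))
    if include_feedback_excitation:
        rng = np.random.default_rng(seed)
        for j in range(n_stellate):
            targets = rng.choice(n_i, size=excit_fanout, replace=False)
            w_ei[j, targets] = g_ei
    spec = NetworkSpec(
        n_stellate=n_stellate,
        n_interneuron=n_i,
        w_ie=w_ie,
        w_ei=w_ei,
        w_ii=_all_to_all(n_i, g_ii),
        iext_s=np.full(n_stellate, float(iext_s)),
        iext_i=np.full(n_i, float(iext_i)),
        groups=np.repeat(np.arange(2), n_per_group),
        name="dual_ring",
    )
    spec.validate()
    return spec
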