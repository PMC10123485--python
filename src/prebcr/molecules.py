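"""Multistate molecular agents and their interaction rate tables.

Three base species are tracked per copy: the pre-B cell receptor (pre-BCR),
the Src-family kinase Lyn, and the cytosolic kinase Syk.  Each receptor
carries two lumped ITAM sites (one for the Igα chain, one for Igβ), each with
phosphorylation status 0, 1 or 2 and a single kinase-occupancy slot.
Receptors are divalent and polymerize into strictly linear chains
(aggregates); trans-phosphorylation is restricted to kinases docked on
immediately adjacent receptors within the same chain.

The rate constants live in module-level tables:

* ``LYN_BINDING`` / ``SYK_BINDING`` — binding radius (μm) and off-rate (/s)
  per (ITAM kind, phosphorylation status) combination.  Lyn binds
  unphosphorylated Igα through its unique domain and phosphorylated
  Igα/Igβ through its SH2 domain; Syk docks only on phosphorylated ITAMs.
* ``PHOSPHO_ITAM`` etc. — kinase rates (/s), indexed by whether the kinase
  itself is activated; activated Lyn is ~3x stronger.
* ``DEPHOSPHO`` — first-order dephosphorylation rates (/s); doubly
  phosphorylated ITAMs dephosphorylate (2 -> 1) at twice the 1 -> 0 rate.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union


class ItamKind(Enum):
    IG_ALPHA = 0
    IG_BETA = 1


class Kinase(Enum):
    LYN = 0
    SYK = 1


class Substrate(Enum):
    IG_ALPHA = 0
    IG_BETA = 1
    LYN_Y397 = 2
    SYK_LINKER = 3
    SYK_CATALYTIC = 4


class BindingMode(Enum):
    NONE = 0
    UNIQUE_DOMAIN = 1
    SH2 = 2


# --- Binding radii (μm) and off-rates (/s) ---------------------------------
# Lyn: unique domain binds unphosphorylated Igα (fast release, 20/s);
# SH2 binds phosphorylated Igα or Igβ (slow release, 0.12/s).  The Igβ
# radius is half the Igα radius (Lyn prefers Igα ~2:1).
LYN_BINDING: dict[tuple[ItamKind, int], tuple[float, float, BindingMode]] = {
    (ItamKind.IG_ALPHA, 0): (2.29e-4, 20.0, BindingMode.UNIQUE_DOMAIN),
    (ItamKind.IG_ALPHA, 1): (2.29e-4, 0.12, BindingMode.SH2),
    (ItamKind.IG_ALPHA, 2): (2.29e-4, 0.12, BindingMode.SH2),
    (ItamKind.IG_BETA, 1): (1.14e-4, 0.12, BindingMode.SH2),
    (ItamKind.IG_BETA, 2): (1.14e-4, 0.12, BindingMode.SH2),
}

# Syk tandem-SH2 docking: larger radius (higher on-rate) and lower off-rate
# on doubly phosphorylated ITAMs; Igα radii are 3x the Igβ radii.
SYK_BINDING: dict[tuple[ItamKind, int], tuple[float, float]] = {
    (ItamKind.IG_ALPHA, 1): (1.31e-4, 2.6),
    (ItamKind.IG_ALPHA, 2): (1.57e-3, 0.3),
    (ItamKind.IG_BETA, 1): (4.37e-5, 2.6),
    (ItamKind.IG_BETA, 2): (5.25e-4, 0.3),
}

# Release rates used when a kinase remains docked while its site has a
# status with no tabulated off-rate (the site was dephosphorylated under
# the bound kinase): the phospho-tyrosine holding the SH2 is gone, so the
# kinase releases quickly.
LYN_OFF_RATE_UNLISTED = 20.0   # /s, Lyn on Igβ status 0
SYK_OFF_RATE_UNLISTED = 2.6    # /s, Syk on a status-0 ITAM

# --- Phosphorylation rates (/s), indexed [kinase_activated][...] ----------
# ITAM sites: first site 0->1, second site 1->2 at half the rate.
PHOSPHO_ITAM = ((30.0, 15.0), (100.0, 50.0))
# Lyn trans-phosphorylating Lyn Y397 and the Syk linker region (Y342/Y346).
PHOSPHO_LYN_Y397 = (30.0, 100.0)
PHOSPHO_SYK_LINKER = (30.0, 100.0)
# Syk trans-phosphorylating the Syk catalytic domain (Y519/Y520); rate
# depends on whether the acting Syk is itself catalytically phosphorylated.
PHOSPHO_SYK_CATALYTIC = (100.0, 200.0)

# --- Dephosphorylation rates (/s) -----------------------------------------
DEPHOSPHO_ITAM = {1: 20.0, 2: 40.0}   # stepwise 2->1 at 40, 1->0 at 20
DEPHOSPHO_LYN_Y397 = 20.0
DEPHOSPHO_SYK = 20.0                  # both Syk sites


def lyn_binding_params(
    itam_kind: ItamKind, phospho_status: int
) -> Optional[tuple[float, float]]:
    """Binding radius (μm) and off-rate (/s) for Lyn on an ITAM site.

    Returns ``None`` when no binding mode exists (Igβ with status 0: the
    unique domain is Igα-specific and the SH2 needs a phospho-tyrosine).
    """
    _check_site(itam_kind, phospho_status)
    entry = LYN_BINDING.get((itam_kind, phospho_status))
    if entry is None:
        return None
    radius, off_rate, _mode = entry
    return radius, off_rate


def lyn_binding_mode(itam_kind: ItamKind, phospho_status: int) -> BindingMode:
    _check_site(itam_kind, phospho_status)
    entry = LYN_BINDING.get((itam_kind, phospho_status))
    return BindingMode.NONE if entry is None else entry[2]


def syk_binding_params(
    itam_kind: ItamKind, phospho_status: int
) -> Optional[tuple[float, float]]:
    """Binding radius (μm) and off-rate (/s) for Syk on an ITAM site.

    ``None`` for unphosphorylated sites: Syk docks only on phospho-ITAMs.
    """
    _check_site(itam_kind, phospho_status)
    return SYK_BINDING.get((itam_kind, phospho_status))


def _check_site(itam_kind: ItamKind, phospho_status: int) -> None:
    if not isinstance(itam_kind, ItamKind):
        raise ValueError(f"invalid ITAM kind: {itam_kind!r}")
    if phospho_status not in (0, 1, 2):
        raise ValueError(f"invalid ITAM phospho status: {phospho_status!r}")


_LEGAL_PAIRS = {
    (Kinase.LYN, Substrate.IG_ALPHA),
    (Kinase.LYN, Substrate.IG_BETA),
    (Kinase.LYN, Substrate.LYN_Y397),
    (Kinase.LYN, Substrate.SYK_LINKER),
    (Kinase.SYK, Substrate.SYK_CATALYTIC),
}


def phospho_rate(
    kinase: Kinase,
    kinase_activated: int,
    substrate: Substrate,
    substrate_status: int,
) -> Optional[float]:
    """Trans-phosphorylation rate (/s) for a docked kinase acting on a
    substrate site of an immediately adjacent receptor.

    Lyn phosphorylates ITAMs, Lyn Y397 and the Syk linker; Syk
    phosphorylates only the Syk catalytic domain.  Returns ``None`` when
    the substrate is already saturated; raises on an illegal pairing.
    """
    if not isinstance(kinase, Kinase) or not isinstance(substrate, Substrate):
        raise ValueError("invalid kinase or substrate enum")
    if kinase_activated not in (0, 1):
        raise ValueError(f"invalid kinase activation flag: {kinase_activated!r}")
    if (kinase, substrate) not in _LEGAL_PAIRS:
        raise ValueError(f"illegal kinase/substrate pairing: {kinase} -> {substrate}")
    if substrate in (Substrate.IG_ALPHA, Substrate.IG_BETA):
        if substrate_status not in (0, 1, 2):
            raise ValueError(f"invalid ITAM status: {substrate_status!r}")
        if substrate_status == 2:
            return None
        return PHOSPHO_ITAM[kinase_activated][substrate_status]
    if substrate_status not in (0, 1):
        raise ValueError(f"invalid binary site status: {substrate_status!r}")
    if substrate_status == 1:
        return None
    if substrate is Substrate.LYN_Y397:
        return PHOSPHO_LYN_Y397[kinase_activated]
    if substrate is Substrate.SYK_LINKER:
        return PHOSPHO_SYK_LINKER[kinase_activated]
    return PHOSPHO_SYK_CATALYTIC[kinase_activated]


def dephospho_rate(substrate: Substrate, status: int) -> float:
    """First-order dephosphorylation rate (/s) for a phosphorylated site."""
    if not isinstance(substrate, Substrate):
        raise ValueError(f"invalid substrate: {substrate!r}")
    if status < 1:
        raise ValueError("status 0: nothing to dephosphorylate")
    if substrate in (Substrate.IG_ALPHA, Substrate.IG_BETA):
        if status not in (1, 2):
            raise ValueError(f"invalid ITAM status: {status!r}")
        return DEPHOSPHO_ITAM[status]
    if status != 1:
        raise ValueError(f"invalid binary site status: {status!r}")
    if substrate is Substrate.LYN_Y397:
        return DEPHOSPHO_LYN_Y397
    return DEPHOSPHO_SYK


# --------------------------------------------------------------------------
# Object-level agent model.  The production engine (dynamics/_kernel) works
# on flat arrays for speed; these dataclasses give the same topology rules a
# direct, inspectable form used for snapshots and tests.
# --------------------------------------------------------------------------


@dataclass
class ItamSite:
    kind: ItamKind
    phospho_status: int = 0
    occupant: object | None = None  # LynState or SykState


@dataclass
class ReceptorState:
    id: int
    itam_alpha: ItamSite = None  # type: ignore[assignment]
    itam_beta: ItamSite = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.itam_alpha is None:
            self.itam_alpha = ItamSite(ItamKind.IG_ALPHA)
        if self.itam_beta is None:
            self.itam_beta = ItamSite(ItamKind.IG_BETA)

    def site(self, kind: ItamKind) -> ItamSite:
        return self.itam_alpha if kind is ItamKind.IG_ALPHA else self.itam_beta


@dataclass
class LynState:
    id: int
    position: tuple[float, float] = (0.0, 0.0)
    y397: int = 0
    bound_site: ItamSite | None = None
    bound_via: BindingMode = BindingMode.NONE


@dataclass
class SykState:
    id: int
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    catalytic_site: int = 0
    linker_site: int = 0
    bound_site: ItamSite | None = None


@dataclass
class AggregateChain:
    """Ordered linear chain of receptors sharing one spatial position.

    A chain of size M diffuses with coefficient D_rec / M; bonds exist only
    between consecutive members (no rings).
    """

    id: int
    member_receptors: list[ReceptorState] = field(default_factory=list)
    position: tuple[float, float] = (0.0, 0.0)

    @property
    def m_agg(self) -> int:
        return len(self.member_receptors)


def merge_chains(
    a: AggregateChain,
    b: AggregateChain,
    position: tuple[float, float] | None = None,
    rng: random.Random | None = None,
) -> AggregateChain:
    """Join two distinct chains end to end (tail of ``a`` to head of ``b``).

    Ring closure (merging a chain with itself) is rejected.  The end
    orientation is randomized: each chain is independently reversed with
    probability 1/2, which leaves all adjacency-derived observables
    unchanged but avoids an arbitrary deterministic head/tail convention.
    """
    if a is b or a.id == b.id:
        raise ValueError("cannot merge a chain with itself (no rings)")
    members_a = list(a.member_receptors)
    members_b = list(b.member_receptors)
    if rng is not None:
        if rng.random() < 0.5:
            members_a.reverse()
        if rng.random() < 0.5:
            members_b.reverse()
    if position is None:
        position = (
            0.5 * (a.position[0] + b.position[0]),
            0.5 * (a.position[1] + b.position[1]),
        )
    return AggregateChain(id=a.id, member_receptors=members_a + members_b,
                          position=position)


def split_chain(
    chain: AggregateChain, bond_index: int
) -> tuple[AggregateChain, AggregateChain]:
    """Break the bond between members ``bond_index`` and ``bond_index+1``.

    Both fragments inherit the parent position; the dynamics engine then
    separates them spatially.  Receptor count is conserved.
    """
    if not 0 <= bond_index < chain.m_agg - 1:
        raise ValueError(
            f"bond_index {bond_index} out of range for chain of size {chain.m_agg}"
        )
    left = AggregateChain(
        id=chain.id,
        member_receptors=chain.member_receptors[: bond_index + 1],
        position=chain.position,
    )
    right = AggregateChain(
        id=-chain.id - 1,
        member_receptors=chain.member_receptors[bond_index + 1 :],
        position=chain.position,
    )
    return left, right


def adjacent_substrates(
    chain: AggregateChain, receptor_index: int
) -> list[tuple[ReceptorState, object]]:
    """Substrate sites reachable by a kinase docked on the receptor at
    ``receptor_index``: the ITAM sites and docked kinases of the immediate
    chain neighbours only.  A kinase never acts on its own receptor, so a
    monomer exposes no substrates (tonic signaling needs aggregation).

    Returns (neighbour receptor, site) pairs where site is an ``ItamSite``
    or a docked ``LynState`` / ``SykState``.
    """
    if not 0 <= receptor_index < chain.m_agg:
        raise ValueError(f"receptor_index {receptor_index} out of range")
    out: list[tuple[ReceptorState, object]] = []
    for j in (receptor_index - 1, receptor_index + 1):
        if 0 <= j < chain.m_agg:
            nb = chain.member_receptors[j]
            for site in (nb.itam_alpha, nb.itam_beta):
                out.append((nb, site))
                if site.occupant is not None:
                    out.append((nb, site.occupant))
    return out
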