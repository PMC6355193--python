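"""The bilateral brainstem-spinal locomotor connectome.

Builds the default network instance: per side the mesencephalic locomotor
region (cuneiform nucleus CnF and pedunculopontine nucleus PPN, each with
glutamatergic and GABA/glycinergic populations), the lateral
paragigantocellular nucleus (LPGi) of the reticular formation with two
glutamatergic subpopulations and one inhibitory population, a vestibular
(VN) population providing constant extensor drive, descending relay
populations (Ine, CINe, dIni) duplicated in cervical and lumbar copies, and
per girdle per side the spinal rhythm generator (flexor centre RG-F,
extensor centre RG-E) with its local interneurons, commissural interneurons
(V0_D, V0_V, V3, CINi) and long propriospinal neurons (LPNs) connecting the
girdles.

Connection weights are dimensionless and signed: positive weights are
excitatory, negative inhibitory, matching the source population's
transmitter type.  The reference weight table stores the default instance's
weights verbatim; entries from the inhibitory relay dIni are kept as magnitudes
and carried with an ``inhibitory`` flag (they are applied with negative
sign).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .population_dynamics import (
    InvalidParameterError,
    NaPParams,
    PopulationSpec,
    SynapseParams,
)

__all__ = [
    "Connection",
    "Network",
    "build_default_network",
    "apply_lesion",
    "perturb_weights",
    "validate_network",
    "build_halfcenter_fixture",
    "REFERENCE_WEIGHTS",
    "INHIBITORY_POPULATIONS",
    "VN_DRIVE",
]

# Constant drive to the vestibular populations keeping extensor centres tonic.
VN_DRIVE = 2.15

# Populations whose outgoing connections are inhibitory.
INHIBITORY_POPULATIONS = frozenset(
    {
        "CnF-GABA/Gly",
        "PPN-GABA/Gly",
        "LPGi-GABA/Gly",
        "InF",
        "InE",
        "Ini",
        "dIni",
        "CINi",
        "V0_D",
        "LPNi",
        "V0_D-LPN",
    }
)

# ---------------------------------------------------------------------------
# The reference connection table, one tuple per (source, target) entry:
#   (source base name, target token, reference weight, section)
# Target tokens: i- ipsilateral, c- contralateral; f- fore, h- hind girdle.
# The dIni entries (section "relay-to-spinal", source "dIni") are stored as
# positive magnitudes of inhibitory connections.
# ---------------------------------------------------------------------------
REFERENCE_WEIGHTS: list[tuple[str, str, float, str]] = [
    # Within brainstem
    ("CnF-Glu", "i-PPN-Glu", 0.56, "brainstem"),
    ("CnF-Glu", "i-LPGi-Glu-1", 0.95, "brainstem"),
    ("CnF-Glu", "i-LPGi-Glu-2", 1.02, "brainstem"),
    ("CnF-Glu", "c-CnF-Glu", 0.1, "brainstem"),
    ("CnF-Glu", "c-PPN-Glu", 0.15, "brainstem"),
    ("CnF-Glu", "c-LPGi-Glu-1", 0.45, "brainstem"),
    ("CnF-Glu", "c-LPGi-Glu-2", 0.08, "brainstem"),
    ("CnF-GABA/Gly", "i-CnF-Glu", -0.5, "brainstem"),
    ("CnF-GABA/Gly", "i-PPN-Glu", -0.5, "brainstem"),
    ("PPN-Glu", "i-LPGi-Glu-1", 1.0, "brainstem"),
    ("PPN-Glu", "c-LPGi-Glu-1", 0.4, "brainstem"),
    ("PPN-GABA/Gly", "i-PPN-Glu", -0.5, "brainstem"),
    ("LPGi-GABA/Gly", "i-LPGi-Glu-1", -0.5, "brainstem"),
    ("LPGi-GABA/Gly", "i-LPGi-Glu-2", -0.5, "brainstem"),
    # Vestibular input to spinal cord
    ("VN", "i-RG-E", 1.0, "vestibular"),
    # From brainstem to relay neurons
    ("LPGi-Glu-1", "i-Ine", 1.0, "brainstem-to-relay"),
    ("LPGi-Glu-1", "i-CINe", 1.0, "brainstem-to-relay"),
    ("LPGi-Glu-2", "i-dIni", 1.0, "brainstem-to-relay"),
    ("LPGi-Glu-2", "c-dIni", 1.0, "brainstem-to-relay"),
    ("LPGi-GABA/Gly", "c-Ine", -0.5, "brainstem-to-relay"),
    ("LPGi-GABA/Gly", "c-CINe", -0.5, "brainstem-to-relay"),
    # From relay neurons to spinal circuits (dIni entries stored as magnitudes)
    ("Ine", "i-RG-F", 1.0, "relay-to-spinal"),
    ("dIni", "i-V0_D", 4.0, "relay-to-spinal"),
    ("dIni", "i-V0_V", 1.7, "relay-to-spinal"),
    ("dIni", "i-f-V0_D-LPN", 7.5, "relay-to-spinal"),
    ("CINe", "c-RG-F", 1.0, "relay-to-spinal"),
    # Within girdle and side of the cord
    ("RG-F", "i-InF", 0.4, "within-girdle"),
    ("RG-F", "i-V0_D", 0.7, "within-girdle"),
    ("RG-F", "i-V2a-lr", 1.0, "within-girdle"),
    ("RG-F", "i-V3", 0.35, "within-girdle"),
    ("RG-F", "i-V2a-diag", 0.5, "within-girdle"),
    ("f-RG-F", "i-LPNi", 0.7, "within-girdle"),
    ("f-RG-F", "i-V0_D-LPN", 0.5, "within-girdle"),
    ("RG-E", "i-InE", 0.4, "within-girdle"),
    ("RG-E", "i-CINi", 0.4, "within-girdle"),
    ("RG-E", "i-Sh2-LPN", 0.5, "within-girdle"),
    ("InF", "i-RG-E", -1.0, "within-girdle"),
    ("InE", "i-RG-F", -0.08, "within-girdle"),
    ("V2a-lr", "i-V0_V", 1.0, "within-girdle"),
    ("V2a-diag", "i-V0_V-LPN", 0.9, "within-girdle"),
    ("Ini", "i-RG-F", -0.075, "within-girdle"),
    # Between left and right circuits within a girdle
    ("V0_D", "c-RG-F", -0.07, "left-right"),
    ("V0_V", "c-Ini", 0.6, "left-right"),
    ("V3", "c-RG-F", 0.03, "left-right"),
    ("CINi", "c-RG-F", -0.03, "left-right"),
    # Between fore and hind circuits
    ("f-LPNi", "ih-RG-F", -0.01, "fore-hind"),
    ("f-Sh2-LPN", "ih-RG-F", 0.01, "fore-hind"),
    ("h-Sh2-LPN", "if-RG-F", 0.075, "fore-hind"),
    ("f-V0_D-LPN", "ch-RG-F", -0.1, "fore-hind"),
    ("f-V0_V-LPN", "ch-RG-F", 0.02, "fore-hind"),
    ("h-V0_V-LPN", "cf-RG-F", 0.065, "fore-hind"),
]

BRAINSTEM_POPULATIONS = {
    "CnF-Glu": "CnF",
    "CnF-GABA/Gly": "CnF",
    "PPN-Glu": "PPN",
    "PPN-GABA/Gly": "PPN",
    "LPGi-Glu-1": "LPGi",
    "LPGi-Glu-2": "LPGi",
    "LPGi-GABA/Gly": "LPGi",
    "VN": "VN",
}
RELAY_POPULATIONS = ("Ine", "CINe", "dIni")
# Spinal populations present in every girdle.
SPINAL_COMMON = (
    "RG-F",
    "RG-E",
    "InF",
    "InE",
    "V0_D",
    "V0_V",
    "V3",
    "CINi",
    "Ini",
    "V2a-lr",
    "V2a-diag",
)
SPINAL_FORE_ONLY = ("LPNi", "V0_D-LPN", "V0_V-LPN", "Sh2-LPN")
SPINAL_HIND_ONLY = ("V0_V-LPN", "Sh2-LPN")

SIDES = ("left", "right")
GIRDLES = ("fore", "hind")
_GIRDLE_OF_RELAY = {"fore": "cervical", "hind": "lumbar"}

# Brainstem regions addressable by lesions and drive protocols.
REGIONS = {
    "CnF": ("CnF-Glu", "CnF-GABA/Gly"),
    "PPN": ("PPN-Glu", "PPN-GABA/Gly"),
    "LPGi": ("LPGi-Glu-1", "LPGi-Glu-2", "LPGi-GABA/Gly"),
    "VN": ("VN",),
}

# Stimulation-target aliases: "LPGi-Glu" drives both glutamatergic LPGi
# subpopulations at once (activation of all LPGi Glu neurons).
STIMULATION_ALIASES = {
    "LPGi-Glu": ("LPGi-Glu-1", "LPGi-Glu-2"),
}


@dataclass(frozen=True)
class Connection:
    """A signed, weighted synaptic connection between two populations."""

    source: str  # canonical key "<name>:<side>[:<girdle>]"
    target: str
    weight: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise InvalidParameterError(f"self-connection on {self.source}")


@dataclass
class Network:
    """Populations, signed weighted connections and drive attachment points."""

    populations: dict[str, PopulationSpec]
    connections: list[Connection]
    constant_drives: dict[str, float] = field(default_factory=dict)
    stimulable: tuple[str, ...] = ()
    synapse: SynapseParams = field(default_factory=SynapseParams)

    def __post_init__(self) -> None:
        for con in self.connections:
            for key in (con.source, con.target):
                if key not in self.populations:
                    raise InvalidParameterError(f"dangling population reference {key!r}")

    @property
    def order(self) -> list[str]:
        """Stable (alphabetical) population ordering for vector layouts."""
        return sorted(self.populations)

    def weight(self, source: str, target: str) -> float:
        """Summed weight of connections from ``source`` onto ``target`` (0 if none)."""
        return sum(c.weight for c in self.connections if c.source == source and c.target == target)

    def weight_matrix(self) -> np.ndarray:
        """Dense signed weight matrix W with W[i, j] = weight from j onto i."""
        idx = {k: i for i, k in enumerate(self.order)}
        w = np.zeros((len(idx), len(idx)))
        for con in self.connections:
            w[idx[con.target], idx[con.source]] += con.weight
        return w

    def drive_vector(self, extra: dict[str, float] | None = None) -> np.ndarray:
        """Per-population total drive in canonical order (constant + extra)."""
        totals = dict(self.constant_drives)
        for key, d in (extra or {}).items():
            totals[key] = totals.get(key, 0.0) + d
        for key in totals:
            if key not in self.populations:
                raise InvalidParameterError(f"drive attached to unknown population {key!r}")
        return np.array([totals.get(k, 0.0) for k in self.order])

    def resolve(self, name: str, side: str) -> list[str]:
        """Keys of populations matching a base name (or alias) and side ('both' allowed)."""
        names = STIMULATION_ALIASES.get(name, (name,))
        sides = SIDES if side == "both" else (side,)
        keys = [
            p.key
            for p in self.populations.values()
            if p.name in names and p.side in sides
        ]
        if not keys:
            raise KeyError(
                f"no population named {name!r} on side {side!r}; "
                f"valid names: {sorted({p.name for p in self.populations.values()})}"
            )
        return sorted(keys)

    def to_frame(self):
        """Connections as a tidy table (source, target, weight) for diffing."""
        import pandas as pd

        return pd.DataFrame(
            [(c.source, c.target, c.weight) for c in self.connections],
            columns=["source", "target", "weight"],
        ).sort_values(["source", "target"], ignore_index=True)


# ---------------------------------------------------------------------------
# Default cell parameters.  Brainstem and relay leak conductance is 5 nS; the
# rhythm-generating centres carry the persistent-sodium current with
# parameters calibrated so that an isolated flexor centre spans roughly
# 2-12 Hz over its operating drive range (see engine.calibrate_rg_center).
# ---------------------------------------------------------------------------

RG_NAP = NaPParams()  # module default; engine calibration can re-derive these
RG_C = 4.5  # pF
RG_G_L = 3.6  # nS
RG_E_L = -64.0  # mV
BRAINSTEM_E_L = -60.0  # mV
RELAY_E_L = -60.0  # mV
SPINAL_E_L = -62.0  # mV
SPINAL_G_L = 2.8  # nS


def _brainstem_spec(name: str, side: str) -> PopulationSpec:
    return PopulationSpec(
        name=name, side=side, compartment=BRAINSTEM_POPULATIONS[name], g_l=5.0,
        e_l=BRAINSTEM_E_L,
    )


def _relay_spec(name: str, side: str, girdle: str) -> PopulationSpec:
    return PopulationSpec(
        name=name,
        side=side,
        compartment=f"relay-{_GIRDLE_OF_RELAY[girdle]}",
        girdle=_GIRDLE_OF_RELAY[girdle],
        g_l=5.0,
        e_l=RELAY_E_L,
    )


def _spinal_spec(name: str, side: str, girdle: str, nap: NaPParams) -> PopulationSpec:
    if name in ("RG-F", "RG-E"):
        return PopulationSpec(
            name=name,
            side=side,
            compartment=f"spinal-{girdle}",
            girdle=girdle,
            dynamics_class="nap-oscillatory",
            C=RG_C,
            g_l=RG_G_L,
            e_l=RG_E_L,
            nap=nap,
        )
    return PopulationSpec(
        name=name, side=side, compartment=f"spinal-{girdle}", girdle=girdle,
        g_l=SPINAL_G_L, e_l=SPINAL_E_L,
    )


def _other_side(side: str) -> str:
    return "right" if side == "left" else "left"


def _parse_target_token(token: str, src_side: str, src_girdle: str | None):
    """Resolve an 'i-/c-' (+ optional 'f-/h-') prefixed target token."""
    rel, rest = token.split("-", 1)
    side = src_side if rel.startswith("i") else _other_side(src_side)
    girdle = src_girdle
    if len(rel) == 2:  # e.g. "ih", "cf"
        girdle = {"f": "fore", "h": "hind"}[rel[1]]
    elif rest[:2] in ("f-", "h-"):
        girdle = {"f": "fore", "h": "hind"}[rest[0]]
        rest = rest[2:]
    return rest, side, girdle


def _expand_reference_row(source: str, token: str, weight: float, section: str):
    """Yield (source_key, target_key, signed_weight) for one reference-table entry."""
    src_girdles = list(GIRDLES)
    if source.startswith(("f-", "h-")):
        src_girdles = ["fore" if source[0] == "f" else "hind"]
        source = source[2:]
    signed = -abs(weight) if source in INHIBITORY_POPULATIONS else weight

    for side in SIDES:
        if section in ("brainstem",):
            name, tgt_side, _ = _parse_target_token(token, side, None)
            yield f"{source}:{side}", f"{name}:{tgt_side}", signed
        elif section in ("vestibular",):
            name, tgt_side, _ = _parse_target_token(token, side, None)
            for girdle in GIRDLES:  # copies in both girdles, identical weight
                yield f"{source}:{side}", f"{name}:{tgt_side}:{girdle}", signed
        elif section == "brainstem-to-relay":
            name, tgt_side, _ = _parse_target_token(token, side, None)
            for girdle in GIRDLES:
                yield (
                    f"{source}:{side}",
                    f"{name}:{tgt_side}:{_GIRDLE_OF_RELAY[girdle]}",
                    signed,
                )
        elif section == "relay-to-spinal":
            for girdle in GIRDLES:
                name, tgt_side, tgt_girdle = _parse_target_token(token, side, girdle)
                if tgt_girdle != girdle:
                    # explicit girdle prefix: only the girdle-matched relay copy projects
                    continue
                yield (
                    f"{source}:{side}:{_GIRDLE_OF_RELAY[girdle]}",
                    f"{name}:{tgt_side}:{tgt_girdle}",
                    signed,
                )
        else:  # spinal sections: within-girdle, left-right, fore-hind
            for girdle in src_girdles:
                name, tgt_side, tgt_girdle = _parse_target_token(token, side, girdle)
                yield f"{source}:{side}:{girdle}", f"{name}:{tgt_side}:{tgt_girdle}", signed


def build_default_network(
    nap: NaPParams | None = None, synapse: SynapseParams | None = None
) -> Network:
    """Construct the complete bilateral default network.

    Every reference-table entry is realised on both sides (and, for
    targets duplicated across girdles, in both cervical and lumbar copies);
    the constant vestibular drive D_VN = 2.15 is attached on both sides.
    """
    nap = nap or RG_NAP
    populations: dict[str, PopulationSpec] = {}
    for side in SIDES:
        for name in BRAINSTEM_POPULATIONS:
            spec = _brainstem_spec(name, side)
            populations[spec.key] = spec
        for girdle in GIRDLES:
            for name in RELAY_POPULATIONS:
                spec = _relay_spec(name, side, girdle)
                populations[spec.key] = spec
            girdle_only = SPINAL_FORE_ONLY if girdle == "fore" else SPINAL_HIND_ONLY
            for name in SPINAL_COMMON + girdle_only:
                spec = _spinal_spec(name, side, girdle, nap)
                populations[spec.key] = spec

    connections = [
        Connection(src, tgt, w)
        for source, token, weight, section in REFERENCE_WEIGHTS
        for src, tgt, w in _expand_reference_row(source, token, weight, section)
    ]

    net = Network(
        populations=populations,
        connections=connections,
        constant_drives={"VN:left": VN_DRIVE, "VN:right": VN_DRIVE},
        stimulable=tuple(
            sorted(BRAINSTEM_POPULATIONS) + sorted(STIMULATION_ALIASES)
        ),
        synapse=synapse or SynapseParams(),
    )
    return net


def apply_lesion(net: Network, regions, sides: str = "both") -> Network:
    """Zero all outgoing connection weights of the given brainstem region(s).

    ``regions`` is a region name ("PPN") or iterable of region and/or
    population names; ``sides`` is "both", "left" or "right".  Returns a new
    network; the input is not mutated.
    """
    if isinstance(regions, str):
        regions = [regions]
    names: set[str] = set()
    for region in regions:
        if region in REGIONS:
            names.update(REGIONS[region])
        elif any(p.name == region for p in net.populations.values()):
            names.add(region)
        else:
            raise KeyError(
                f"unknown region or population {region!r}; valid regions: "
                f"{sorted(REGIONS)}; valid populations: "
                f"{sorted({p.name for p in net.populations.values()})}"
            )
    side_set = set(SIDES) if sides == "both" else {sides}
    lesioned = {
        key for key, p in net.populations.items() if p.name in names and p.side in side_set
    }
    new = copy.deepcopy(net)
    new.connections = [
        Connection(c.source, c.target, 0.0) if c.source in lesioned else c
        for c in net.connections
    ]
    return new


def perturb_weights(net: Network, sigma_p: float, seed) -> Network:
    """Multiply every connection weight by an independent N(1, sigma_p) draw.

    Mirror symmetry is deliberately not preserved: each connection gets its
    own multiplier.  Draws may flip a weight's sign at large sigma_p; such
    networks are kept as drawn.  Returns a new network.
    """
    if sigma_p < 0:
        raise InvalidParameterError("sigma_p must be >= 0")
    rng = np.random.default_rng(seed)
    multipliers = rng.normal(1.0, sigma_p, size=len(net.connections))
    new = copy.deepcopy(net)
    new.connections = [
        Connection(c.source, c.target, c.weight * m)
        for c, m in zip(net.connections, multipliers)
    ]
    return new


def _mirror_key(key: str) -> str:
    name, side, *girdle = key.split(":")
    return ":".join([name, _other_side(side), *girdle])


def validate_network(net: Network) -> list[str]:
    """Structural checks; returns a list of human-readable violations.

    Checks left/right mirror symmetry of connections and drives, the
    sign-vs-transmitter rule, and dangling references in drives.
    """
    violations: list[str] = []
    weights: dict[tuple[str, str], float] = {}
    for c in net.connections:
        weights[(c.source, c.target)] = weights.get((c.source, c.target), 0.0) + c.weight
    for (src, tgt), w in weights.items():
        hom = (_mirror_key(src), _mirror_key(tgt))
        if hom not in weights:
            violations.append(f"missing mirror homolog of {src} -> {tgt}")
        elif abs(weights[hom] - w) > 1e-12:
            violations.append(
                f"mirror asymmetry {src} -> {tgt}: {w} vs {weights[hom]}"
            )
        src_name = src.split(":")[0]
        inhibitory = src_name in INHIBITORY_POPULATIONS
        if w != 0.0 and (w < 0) != inhibitory:
            kind = "inhibitory" if inhibitory else "excitatory"
            violations.append(f"sign violation: {kind} source {src} -> {tgt} weight {w}")
    for key in net.constant_drives:
        if key not in net.populations:
            violations.append(f"constant drive attached to unknown population {key}")
        elif key != _mirror_key(key) and _mirror_key(key) not in net.constant_drives:
            violations.append(f"constant drive on {key} lacks mirror homolog")
    return violations


def build_halfcenter_fixture(
    drive: float = 0.0,
    weight: float = -0.5,
    nap: NaPParams | None = None,
    synapse: SynapseParams | None = None,
) -> Network:
    """Two identical mutually inhibiting oscillatory populations under a shared drive.

    The canonical half-centre test fixture: reciprocal inhibition of strength
    ``weight`` (negative) between two flexor-centre-like populations, each
    receiving the same excitatory drive.
    """
    if drive < 0:
        raise InvalidParameterError("drive must be >= 0")
    nap = nap or RG_NAP
    specs = {}
    for side in SIDES:
        spec = PopulationSpec(
            name="HC",
            side=side,
            compartment="spinal-hind",
            girdle="hind",
            dynamics_class="nap-oscillatory",
            C=RG_C,
            g_l=RG_G_L,
            e_l=RG_E_L,
            nap=nap,
        )
        specs[spec.key] = spec
    connections = [
        Connection("HC:left:hind", "HC:right:hind", -abs(weight)),
        Connection("HC:right:hind", "HC:left:hind", -abs(weight)),
    ]
    return Network(
        populations=specs,
        connections=connections,
        constant_drives={"HC:left:hind": drive, "HC:right:hind": drive},
        stimulable=("HC",),
        synapse=synapse or SynapseParams(),
    )
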