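"""Motor cortico-basal-ganglia network definition and parameter priors.

The modelled circuit has four nodes — primary motor cortex (M1), motor
putamen (PUT), subthalamic nucleus (STN) and motor thalamus (THAL) — joined
by six directed couplings that caricature the classical direct, indirect and
hyperdirect routes through the basal ganglia, plus an inhibitory
self-connection on every node.  All coupling matrices in this package are
oriented ``A[target, source]`` with the node order fixed as
(M1, PUT, STN, THAL).

The free parameters of the generative model are collected in
:class:`DCMParams`: signed between-node couplings in Hz, log-scalers for the
(always negative) self-connections, per-node log-scalers of hemodynamic
delay, a shared neuronal noise (log-amplitude, log-exponent) pair, and a
per-node observation-noise log-amplitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODES: tuple[str, ...] = ("M1", "PUT", "STN", "THAL")

#: Canonical directed between-node edges (source, target).
CANONICAL_EDGES: tuple[tuple[str, str], ...] = (
    ("M1", "PUT"),
    ("M1", "STN"),
    ("PUT", "THAL"),
    ("PUT", "STN"),
    ("STN", "THAL"),
    ("THAL", "M1"),
)

#: Baseline self-connection strength: a_ii = -0.5 * exp(self_log) Hz.
SELF_BASE_HZ = -0.5

# Prior variances (diagonal): shrinkage scales comparable to reference
# cross-spectral DCM implementations.
PRIOR_VAR_COUPLING = 1.0 / 16.0
PRIOR_VAR_OTHER = 1.0 / 64.0


class UnmappedEdgeError(ValueError):
    """An edge cannot be assigned to a pathway role."""


@dataclass(frozen=True)
class NetworkSpec:
    """Directed graph of the modelled circuit.

    Parameters
    ----------
    node_labels : ordered node names, always length 4 here.
    edges : ordered (source, target) pairs; between-node couplings.
    self_connections : one flag per node; always on in this model.
    """

    node_labels: tuple[str, ...] = NODES
    edges: tuple[tuple[str, str], ...] = CANONICAL_EDGES
    self_connections: tuple[bool, ...] = (True, True, True, True)

    def __post_init__(self):
        if len(self.node_labels) != len(self.self_connections):
            raise ValueError("one self-connection flag per node required")
        for s, t in self.edges:
            if s not in self.node_labels or t not in self.node_labels:
                raise ValueError(f"edge ({s}, {t}) references unknown node")
            if s == t:
                raise ValueError("self-loops are modelled separately")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edge")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, name: str) -> int:
        return self.node_labels.index(name)

    def edge_index(self, source: str, target: str) -> int:
        return self.edges.index((source, target))

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": list(self.node_labels),
            "edges": [list(e) for e in self.edges],
            "self_connections": list(self.self_connections),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            node_labels=tuple(d["nodes"]),
            edges=tuple((s, t) for s, t in d["edges"]),
            self_connections=tuple(d.get("self_connections", [True] * len(d["nodes"]))),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class PathwayMap:
    """Assignment of each between-node edge to a basal-ganglia pathway role."""

    direct: tuple[tuple[str, str], ...]
    indirect: tuple[tuple[str, str], ...]
    hyperdirect: tuple[tuple[str, str], ...]
    input: tuple[str, str]
    output: tuple[str, str]

    def role_of(self, edge: tuple[str, str]) -> str:
        if edge in self.direct:
            return "direct pathway"
        if edge in self.indirect:
            return "indirect pathway"
        if edge in self.hyperdirect:
            return "hyperdirect pathway"
        if edge == self.input:
            return "cortico-striatal input"
        if edge == self.output:
            return "thalamo-cortical output"
        raise UnmappedEdgeError(f"edge {edge} has no pathway role")


def build_bg_network() -> NetworkSpec:
    """Return the canonical 4-node basal ganglia A-matrix specification.

    Six between-node couplings: the cortico-striatal input M1->PUT, the
    hyperdirect M1->STN, the direct-pathway PUT->THAL, the two indirect
    components PUT->STN and STN->THAL, and the thalamo-cortical return
    THAL->M1.  Every node carries an inhibitory self-connection.
    """
    return NetworkSpec()


def pathway_map(spec: NetworkSpec) -> PathwayMap:
    """Partition a network's edges into pathway roles.

    Raises
    ------
    UnmappedEdgeError
        If the network contains an edge outside the canonical partition
        (every between-node edge must carry exactly one role).
    """
    pm = PathwayMap(
        direct=(("PUT", "THAL"),),
        indirect=(("PUT", "STN"), ("STN", "THAL")),
        hyperdirect=(("M1", "STN"),),
        input=("M1", "PUT"),
        output=("THAL", "M1"),
    )
    for e in spec.edges:
        pm.role_of(e)  # raises on unmapped edge
    return pm


# ---------------------------------------------------------------------------
# Parameter vector layout
# ---------------------------------------------------------------------------

@dataclass
class ParamLayout:
    """Index map from named parameter blocks into the flat parameter vector.

    Order: couplings (one per edge), self_log (per node), hemo_delay_log
    (per node), neuronal noise (log-amplitude, log-exponent), observation
    noise log-amplitude (per node).
    """

    spec: NetworkSpec = field(default_factory=build_bg_network)

    @property
    def n_coupling(self) -> int:
        return self.spec.n_edges

    @property
    def n_nodes(self) -> int:
        return self.spec.n_nodes

    @property
    def dim(self) -> int:
        return self.n_coupling + 2 * self.n_nodes + 2 + self.n_nodes

    @property
    def sl_coupling(self) -> slice:
        return slice(0, self.n_coupling)

    @property
    def sl_self(self) -> slice:
        return slice(self.n_coupling, self.n_coupling + self.n_nodes)

    @property
    def sl_hemo(self) -> slice:
        a = self.n_coupling + self.n_nodes
        return slice(a, a + self.n_nodes)

    @property
    def sl_neuronal(self) -> slice:
        a = self.n_coupling + 2 * self.n_nodes
        return slice(a, a + 2)

    @property
    def sl_obs(self) -> slice:
        a = self.n_coupling + 2 * self.n_nodes + 2
        return slice(a, a + self.n_nodes)

    def names(self) -> list[str]:
        out = [f"{s}->{t}" for s, t in self.spec.edges]
        out += [f"self_{n}" for n in self.spec.node_labels]
        out += [f"hemo_{n}" for n in self.spec.node_labels]
        out += ["neuro_logamp", "neuro_logexp"]
        out += [f"obs_{n}" for n in self.spec.node_labels]
        return out


@dataclass
class DCMParams:
    """Free parameters of the generative model, as a structured view.

    ``coupling`` is in Hz per edge (positive = excitatory influence of the
    source on the rate of change of the target; negative = inhibitory).
    Self-connections are ``-0.5 * exp(self_log)`` Hz, negative for any
    finite ``self_log``.
    """

    coupling: np.ndarray
    self_log: np.ndarray
    hemo_delay_log: np.ndarray
    noise_neuronal: np.ndarray  # (log-amplitude, log-exponent)
    noise_observation: np.ndarray  # log-amplitude per node
    layout: ParamLayout = field(default_factory=ParamLayout)

    @classmethod
    def from_vector(cls, theta: np.ndarray, layout: ParamLayout | None = None) -> "DCMParams":
        lo = layout or ParamLayout()
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (lo.dim,):
            raise ValueError(f"expected parameter vector of length {lo.dim}")
        return cls(
            coupling=theta[lo.sl_coupling].copy(),
            self_log=theta[lo.sl_self].copy(),
            hemo_delay_log=theta[lo.sl_hemo].copy(),
            noise_neuronal=theta[lo.sl_neuronal].copy(),
            noise_observation=theta[lo.sl_obs].copy(),
            layout=lo,
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.coupling, self.self_log, self.hemo_delay_log,
             self.noise_neuronal, self.noise_observation]
        )

    def self_coupling(self) -> np.ndarray:
        """Self-connection strengths in Hz (strictly negative)."""
        return SELF_BASE_HZ * np.exp(self.self_log)

    def a_matrix(self) -> np.ndarray:
        """Assemble the coupling matrix A with A[target, source] orientation."""
        spec = self.layout.spec
        n = spec.n_nodes
        A = np.zeros((n, n))
        for k, (s, t) in enumerate(spec.edges):
            A[spec.node_index(t), spec.node_index(s)] = self.coupling[k]
        A[np.diag_indices(n)] = self.self_coupling()
        return A


@dataclass
class PriorDensity:
    """Diagonal Gaussian prior over the flat parameter vector."""

    mean: np.ndarray
    var: np.ndarray  # diagonal of the covariance

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.mean.shape != self.var.shape:
            raise ValueError("mean/var dimension mismatch")
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be strictly positive")

    @property
    def dim(self) -> int:
        return self.mean.size

    @property
    def covariance(self) -> np.ndarray:
        return np.diag(self.var)

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "var": self.var.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorDensity":
        return cls(mean=np.array(d["mean"]), var=np.array(d["var"]))


def default_priors(spec: NetworkSpec | None = None,
                   freeze_hemo: bool = False) -> PriorDensity:
    """Zero-mean shrinkage priors over all model parameters.

    Couplings get variance 1/16 Hz^2; log-scaling parameters (self, hemo
    delay, noise) get variance 1/64.  The zero prior mean implies a
    -0.5 Hz self-connection, unit hemodynamic delay scaling and pink
    (1/f) noise on every node.  With ``freeze_hemo`` the hemodynamic delay
    scalers are pinned near the prior mean (variance 1e-8), effectively
    fixing the hemodynamics per region.
    """
    layout = ParamLayout(spec or build_bg_network())
    var = np.full(layout.dim, PRIOR_VAR_OTHER)
    var[layout.sl_coupling] = PRIOR_VAR_COUPLING
    if freeze_hemo:
        var[layout.sl_hemo] = 1e-8
    return PriorDensity(mean=np.zeros(layout.dim), var=var)


def model_to_json(spec: NetworkSpec, priors: PriorDensity, path: str | Path) -> None:
    """Write a model file (nodes, edges, priors) as a single JSON document."""
    doc = spec.to_dict()
    doc["priors"] = priors.to_dict()
    Path(path).write_text(json.dumps(doc, indent=1))


def model_from_json(path: str | Path) -> tuple[NetworkSpec, PriorDensity]:
    doc = json.loads(Path(path).read_text())
    spec = NetworkSpec.from_dict(doc)
    if "priors" in doc:
        priors = PriorDensity.from_dict(doc["priors"])
    else:
        priors = default_priors(spec)
    return spec, priors
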