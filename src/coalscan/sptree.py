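"""Species-tree model for the multispecies coalescent simulator.

A :class:`SpeciesTreeModel` is a rooted binary ultrametric tree over taxon
labels with, per branch, a duration in generations and a diploid effective
population size Ne.  Time runs backwards from the present (tip age 0);
pairwise coalescence within a branch occurs at rate 1/(2 Ne) per pair per
generation.  Directed admixture pulses (:class:`AdmixturePulse`) move
lineages, backwards in time, from the recipient branch into the donor
branch with probability gamma.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["SpeciesTreeModel", "AdmixturePulse", "SimulationConfig", "default_panel"]


@dataclass(frozen=True)
class AdmixturePulse:
    """A single directed admixture pulse.

    ``proportion`` (gamma) is the fraction of the recipient population
    replaced by donor migrants at ``time`` generations before present.
    Backwards in time, each lineage found in the recipient branch at the
    pulse time migrates to the donor branch independently with
    probability gamma.
    """

    donor: str
    recipient: str
    time: float
    proportion: float

    def __post_init__(self):
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"pulse proportion {self.proportion} outside [0, 1]")
        if self.time < 0:
            raise ValueError("pulse time must be non-negative")


class SpeciesTreeModel:
    """Rooted binary ultrametric species tree with per-branch Ne.

    Internally nodes are indexed 0..2n-2 with tips first (in label order of
    first appearance in the newick) and internal nodes sorted by age, the
    root last.  ``node_time`` holds node ages in generations, ``node_ne``
    the Ne of the branch *above* each node (the root entry is the ancestral
    Ne, extending indefinitely into the past).
    """

    def __init__(
        self,
        labels: list[str],
        parent: np.ndarray,
        node_time: np.ndarray,
        node_ne: np.ndarray,
        mu: float,
        outgroup: str,
    ):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int32)
        self.node_time = np.asarray(node_time, dtype=np.float64)
        self.node_ne = np.asarray(node_ne, dtype=np.float64)
        self.mu = float(mu)
        self.outgroup = outgroup
        self._validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(
        cls,
        newick: str,
        *,
        ne: float | dict[str, float],
        mu: float,
        outgroup: str,
    ) -> "SpeciesTreeModel":
        """Build from a newick string whose branch lengths are durations in
        generations.  ``ne`` is a single value for every branch or a map
        from tip/internal-node label to the Ne of the branch above it
        (missing entries fall back to ``ne['*']``)."""
        tree = dendropy.Tree.get(data=newick, schema="newick")
        # node ages from branch durations, bottom-up
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                nd.age_gen = 0.0
            else:
                ages = [
                    ch.age_gen + (ch.edge.length if ch.edge.length is not None else 0.0)
                    for ch in nd.child_nodes()
                ]
                if max(ages) - min(ages) > 1e-6 * max(max(ages), 1.0):
                    raise ValueError(
                        f"species tree not ultrametric at node with child ages {ages}"
                    )
                nd.age_gen = float(np.mean(ages))

        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate taxon labels")
        n = len(tips)
        tip_index = {lab: i for i, lab in enumerate(tips)}
        internals = sorted(
            (nd for nd in tree.preorder_node_iter() if not nd.is_leaf()),
            key=lambda nd: nd.age_gen,
        )
        node_of = {}
        for nd in tree.leaf_node_iter():
            node_of[id(nd)] = tip_index[nd.taxon.label]
        for k, nd in enumerate(internals):
            node_of[id(nd)] = n + k

        m = 2 * n - 1
        parent = np.full(m, -1, dtype=np.int32)
        node_time = np.zeros(m, dtype=np.float64)
        for nd in tree.preorder_node_iter():
            i = node_of[id(nd)]
            node_time[i] = nd.age_gen
            if nd.parent_node is not None:
                parent[i] = node_of[id(nd.parent_node)]

        if isinstance(ne, dict):
            default = ne.get("*")
            ne_arr = np.empty(m)
            for nd in tree.preorder_node_iter():
                i = node_of[id(nd)]
                lab = nd.taxon.label if nd.is_leaf() else (nd.label or None)
                val = ne.get(lab, default)
                if val is None:
                    raise ValueError(f"no Ne for node {lab!r} and no '*' default")
                ne_arr[i] = val
        else:
            ne_arr = np.full(m, float(ne))
        return cls(tips, parent, node_time, ne_arr, mu=mu, outgroup=outgroup)

    def _validate(self) -> None:
        n = self.n_taxa
        if self.outgroup not in self.labels:
            raise ValueError(f"outgroup {self.outgroup!r} not among taxa")
        if np.any(self.node_ne <= 0):
            raise ValueError("all Ne must be positive")
        if np.any(self.node_time[:n] != 0):
            raise ValueError("tips must have age 0 (ultrametric from present)")
        if np.any(np.diff(self.node_time[n:]) < 0):
            raise ValueError("internal nodes must be sorted by age")
        for i in range(2 * n - 2):
            if self.node_time[self.parent[i]] < self.node_time[i]:
                raise ValueError("parent older than child required")
        # outgroup must attach at the root
        og = self.labels.index(self.outgroup)
        if self.parent[og] != self.root:
            raise ValueError("outgroup must attach directly at the root")

    # -- views -------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return 2 * self.n_taxa - 2

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(2 * self.n_taxa - 1)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                out[p].append(i)
        return out

    def branch_at(self, label: str, time: float) -> int:
        """Species-tree branch (node id) ancestral to ``label`` whose time
        interval [node age, parent age) contains ``time``."""
        i = self.labels.index(label)
        while True:
            p = self.parent[i]
            top = np.inf if p < 0 else self.node_time[p]
            if self.node_time[i] <= time < top:
                return i
            if p < 0:
                raise ValueError(f"time {time} beyond the root for {label}")
            i = p

    def internal_branch_coal_units(self, node: int) -> float:
        """Duration of the branch above ``node`` in coalescent units
        t / (2 Ne)."""
        p = self.parent[node]
        if p < 0:
            return np.inf
        return (self.node_time[p] - self.node_time[node]) / (2.0 * self.node_ne[node])

    def as_gene_tree(self):
        """The species topology as a GeneTree (for quartet constraints,
        RF comparisons against inferred trees, etc.)."""
        from .gtree import GeneTree

        return GeneTree.from_times(self.labels, self.parent, self.node_time)

    def to_newick(self) -> str:
        ch = self.children()

        def rec(i: int) -> str:
            if i < self.n_taxa:
                s = self.labels[i]
            else:
                s = "(" + ",".join(rec(c) for c in ch[i]) + ")"
            p = self.parent[i]
            if p >= 0:
                s += f":{self.node_time[p] - self.node_time[i]:.6g}"
            return s

        return rec(self.root) + ";"


@dataclass
class SimulationConfig:
    """Everything needed for one reproducible synthetic genome."""

    model: SpeciesTreeModel
    pulses: list[AdmixturePulse] = field(default_factory=list)
    n_windows: int = 5000
    window_length: int = 5000
    seed: int = 1
    ploidy: str = "haploid"  # "haploid" | "diploid"
    chrom: str = "1"
    # optional per-window recombination covariate driving intra-window
    # tree churn (sub-window recombination); see simulate.simulate_genome
    subwindow_recombination: bool = False
    bins_per_window: int = 8     # sub-window bins that may share gene trees
    recomb_rate_meanlog: float = 0.0
    recomb_rate_sdlog: float = 0.7
    churn_per_rate: float = 3.0  # E[intra-window breakpoints] per unit rate

    def __post_init__(self):
        if self.n_windows < 1 or self.window_length < 1:
            raise ValueError("n_windows and window_length must be >= 1")
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError("ploidy must be 'haploid' or 'diploid'")
        for p in self.pulses:
            for lab in (p.donor, p.recipient):
                if lab not in self.model.labels:
                    raise ValueError(f"pulse references unknown taxon {lab!r}")
            # branch_at raises if the pulse predates a branch's origin
            self.model.branch_at(p.donor, p.time)
            self.model.branch_at(p.recipient, p.time)


# taxon panel mirroring a single-genome-per-taxon suid study design:
# six Eurasian wild boar population samples (EUR, JPN, NCH, SCH plus a
# second European individual), four island species (a Javan warty pig,
# a bearded pig, a Visayan warty pig and a Sulawesi warty pig), and an
# African warthog outgroup attached at the root.
_PANEL_NEWICK = (
    "((((((((EUA:100000,EUB:100000):80000,JPN:180000):80000,"
    "NCH:260000):80000,SCH:340000):160000,SUM:500000):300000,"
    "VER:800000):350000,(BAR:950000,(CEL:700000,CEB:700000):250000):200000)"
    ":1450000,WAR:2600000);"
)


def default_panel(ne: float = 1.0e5, mu: float = 1.0e-9) -> SpeciesTreeModel:
    """The bundled 10-ingroup-taxa + outgroup demo species tree.

    Split times (0.1-2.6 Myr in generations at ~1 generation unit each
    1e5..2.6e6) and a constant Ne of 1e5 give internal branches of
    0.4-2.2 coalescent units, i.e. appreciable incomplete lineage sorting
    throughout the ingroup, while mu = 1e-9 per site per generation keeps
    per-window variant counts at desk scale.
    """
    return SpeciesTreeModel.from_newick(
        _PANEL_NEWICK, ne=ne, mu=mu, outgroup="WAR"
    )
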