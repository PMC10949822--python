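"""Synthetic ensembles of community CLDs with a planted common core.

Real multi-community diagram collections are rarely shareable, so pipeline
behaviour is validated on generated ensembles whose ground truth is known:
a weakly connected, cyclic core diagram shared (probabilistically) by all
communities, plus community-specific noise variables and links that no
second community corroborates.  Polarity is a property of each planted
link, identical wherever the link appears, so merges are conflict-free by
construction — mirroring the protocol in which polarity conflicts are
resolved with the map builders before merging.

Defaults emulate a 13-community study with on the order of 290 unique
variables and 1,000+ unique links after merging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import CLD, canonical_key
from .vocabulary import VocabularyMap

__all__ = ["EnsembleConfig", "GroundTruth", "generate_ensemble", "recovery_metrics"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Knobs of the generator.

    n_communities: number of community diagrams (13 as in the emulated study).
    core_variables / core_links: size of the shared core diagram (the core
        is a random weakly connected digraph: spanning tree with random arc
        orientations plus extra random arcs, so it is cyclic and connected
        like real community CLDs).
    core_inclusion_prob: probability each community includes a given core link.
    noise_variables_per_community / noise_links_per_community: community-
        unique material; every noise link touches at least one noise
        variable, so its merged count is exactly 1.
    negative_polarity_prob: probability a planted link is negative.
    synonym_noise_prob: probability a community refers to a core variable by
        its raw synonym instead of the canonical name (the emitted
        vocabulary reverses this).
    """

    n_communities: int = 13
    core_variables: int = 25
    core_links: int = 60
    core_inclusion_prob: float = 0.7
    noise_variables_per_community: int = 20
    noise_links_per_community: int = 75
    negative_polarity_prob: float = 0.2
    synonym_noise_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("core_inclusion_prob", "negative_polarity_prob",
                     "synonym_noise_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("n_communities", "core_variables",
                     "noise_variables_per_community"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.core_links < 0 or self.noise_links_per_community < 0:
            raise ValueError("link counts must be non-negative")
        n = self.core_variables
        if self.core_links and self.core_links < n - 1:
            raise ValueError(
                f"core_links={self.core_links} cannot connect "
                f"{n} core variables (need >= {n - 1})")
        if self.core_links > n * (n - 1):
            raise ValueError("core_links exceeds the number of ordered pairs")
        nv = self.noise_variables_per_community
        max_noise = nv * (nv - 1) + 2 * nv * self.core_variables
        if self.noise_links_per_community > max_noise:
            raise ValueError(
                f"noise_links_per_community={self.noise_links_per_community} "
                f"exceeds available noise-anchored pairs ({max_noise})")


@dataclass
class GroundTruth:
    """What was planted, for auditing recovery.

    Link keys are canonical ``(source, target)`` pairs; ``polarity`` maps
    each core link to its planted sign; inclusion counts record how many
    communities actually drew each core link / contained each variable.
    """

    core_variables: tuple[str, ...]
    core_links: tuple[tuple[str, str], ...]
    polarity: dict[tuple[str, str], int]
    link_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    variable_counts: dict[str, int] = field(default_factory=dict)
    synonyms: dict[str, str] = field(default_factory=dict)
    n_unique_variables: int = 0
    n_unique_links: int = 0

    @property
    def core_variable_keys(self) -> frozenset[str]:
        return frozenset(canonical_key(v) for v in self.core_variables)

    @property
    def core_link_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset((canonical_key(s), canonical_key(t))
                         for s, t in self.core_links)

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "core_variables": list(self.core_variables),
            "core_links": [
                {"source": s, "target": t, "polarity": self.polarity[(s, t)],
                 "communities": self.link_counts.get((s, t), 0)}
                for s, t in self.core_links
            ],
            "variable_counts": dict(sorted(self.variable_counts.items())),
            "synonyms": self.synonyms,
            "n_unique_variables": self.n_unique_variables,
            "n_unique_links": self.n_unique_links,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def _core_graph(config: EnsembleConfig, rng: np.random.Generator):
    """Random weakly connected digraph: oriented spanning tree + extra arcs."""
    n = config.core_variables
    order = rng.permutation(n)
    edges: list[tuple[int, int]] = []
    taken: set[tuple[int, int]] = set()
    for i in range(1, n):
        child = int(order[i])
        parent = int(order[rng.integers(0, i)])
        edge = (parent, child) if rng.random() < 0.5 else (child, parent)
        edges.append(edge)
        taken.add(edge)
    candidates = [(a, b) for a in range(n) for b in range(n)
                  if a != b and (a, b) not in taken]
    extra = config.core_links - len(edges)
    if extra > 0:
        chosen = rng.choice(len(candidates), size=extra, replace=False)
        for idx in sorted(int(c) for c in chosen):
            edges.append(candidates[idx])
    return edges


def generate_ensemble(config: EnsembleConfig | None = None, **overrides):
    """Generate community CLDs, their ground truth, and the reversing vocabulary.

    Returns ``(clds, truth, vocab)``.  Deterministic in ``config.seed``:
    identical seeds yield identical ensembles.
    """
    if config is None:
        config = EnsembleConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)

    core_names = tuple(f"core factor {i + 1:02d}"
                       for i in range(config.core_variables))
    aliases = {name: f"{name} (local term)" for name in core_names}

    core_edges = _core_graph(config, rng) if config.core_links else []
    polarity = {}
    core_links = []
    for a, b in core_edges:
        link = (core_names[a], core_names[b])
        core_links.append(link)
        polarity[link] = -1 if rng.random() < config.negative_polarity_prob else 1

    truth = GroundTruth(core_variables=core_names,
                        core_links=tuple(core_links), polarity=polarity)
    clds: list[CLD] = []
    used_aliases: dict[str, str] = {}
    unique_links: set[tuple[str, str]] = set()

    for c in range(config.n_communities):
        cld_id = f"community-{c + 1:02d}"
        included = [link for link in core_links
                    if rng.random() < config.core_inclusion_prob]
        community_core = sorted({v for link in included for v in link},
                                key=core_names.index)
        noise_vars = [f"{cld_id} local issue {j + 1:02d}"
                      for j in range(config.noise_variables_per_community)]

        # noise links: anchored on >= 1 community-unique variable, so each
        # occurs in exactly one diagram and merges with |count| == 1
        pool = community_core + noise_vars
        candidates = [(s, t) for s in pool for t in pool
                      if s != t and (s in noise_vars or t in noise_vars)]
        n_noise = min(config.noise_links_per_community, len(candidates))
        chosen = rng.choice(len(candidates), size=n_noise, replace=False)
        noise_links = [candidates[int(i)] for i in sorted(int(x) for x in chosen)]
        noise_polarity = {
            link: (-1 if rng.random() < config.negative_polarity_prob else 1)
            for link in noise_links}

        # community's spelling of each core variable (synonym noise)
        spelling = {}
        for name in community_core:
            if rng.random() < config.synonym_noise_prob:
                spelling[name] = aliases[name]
                used_aliases[aliases[name]] = name
            else:
                spelling[name] = name

        cld = CLD(cld_id)
        for name in community_core:
            cld.add_variable(spelling[name])
        for name in noise_vars:
            cld.add_variable(name)
        for s, t in included:
            cld.add_link(spelling.get(s, s), spelling.get(t, t), polarity[(s, t)])
            truth.link_counts[(s, t)] = truth.link_counts.get((s, t), 0) + 1
        for s, t in noise_links:
            cld.add_link(spelling.get(s, s), spelling.get(t, t),
                         noise_polarity[(s, t)])
        clds.append(cld)

        for name in community_core:
            truth.variable_counts[name] = truth.variable_counts.get(name, 0) + 1
        unique_links.update((canonical_key(s), canonical_key(t))
                            for s, t in included)
        unique_links.update((canonical_key(s), canonical_key(t))
                            for s, t in noise_links)

    truth.synonyms = dict(used_aliases)
    # unique variables after canonicalisation = core present + all noise vars
    truth.n_unique_variables = (len(truth.variable_counts)
                                + config.n_communities
                                * config.noise_variables_per_community)
    truth.n_unique_links = len(unique_links)

    vocab = VocabularyMap({alias: name for alias, name in used_aliases.items()})
    return clds, truth, vocab


def recovery_metrics(summary, truth: GroundTruth) -> dict[str, float]:
    """Precision/recall of the pared summary against the planted core.

    Variables are compared as canonical-name sets, links as ordered
    canonical pairs.  An empty prediction set has precision 1.0 by
    convention (nothing asserted, nothing wrong) — flagged by the paired
    recall of 0.
    """
    pred_vars = {canonical_key(v) for v in summary.variables}
    true_vars = set(truth.core_variable_keys)
    pred_links = set(summary.link_keys)
    true_links = set(truth.core_link_keys)

    def _precision(pred, true):
        return len(pred & true) / len(pred) if pred else 1.0

    def _recall(pred, true):
        return len(pred & true) / len(true) if true else 1.0

    return {
        "variable_precision": _precision(pred_vars, true_vars),
        "variable_recall": _recall(pred_vars, true_vars),
        "link_precision": _precision(pred_links, true_links),
        "link_recall": _recall(pred_links, true_links),
    }


def config_to_dict(config: EnsembleConfig) -> dict:
    return asdict(config)
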