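"""Hub statistics over archives of optimal spanning trees.

Different co-optimal trees can promote different nodes to high degree, so a
single tree is a poor basis for calling hubs.  Instead the per-node degree is
averaged over *all* archived optimal trees; nodes with high average degree
are the hubs — the structural bottlenecks through which most shortest
pathways of the dense trees run.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dst_optimizer import TreeArchive

__all__ = ["HubProfile", "average_degrees", "rank_hubs", "write_profile_tsv",
           "plot_profile"]


@dataclass
class HubProfile:
    """Average tree degree per node across an archive of optimal trees."""

    nodes: list[str]
    avg_degree: dict[str, float]
    archive_size: int

    @property
    def ranking(self) -> list[str]:
        """Nodes by descending average degree, ties broken alphabetically."""
        return sorted(self.nodes, key=lambda v: (-self.avg_degree[v], v))


def average_degrees(archive: TreeArchive) -> HubProfile:
    """Mean tree degree of every node over all archived trees.

    The averages always sum to ``2 (N - 1)`` (handshake lemma preserved under
    the mean).  Raises ``ValueError`` on an empty archive.
    """
    if len(archive) == 0:
        raise ValueError("empty tree archive: no degrees to average")
    graph = archive.trees[0].graph
    nodes = list(graph.nodes)
    totals = {v: 0 for v in nodes}
    for tree in archive.trees:
        if tree.graph.nodes != nodes:
            raise ValueError("archive mixes trees over different node sets")
        for v, d in tree.degrees().items():
            totals[v] += d
    k = len(archive.trees)
    return HubProfile(
        nodes=nodes,
        avg_degree={v: totals[v] / k for v in nodes},
        archive_size=k,
    )


def rank_hubs(
    profile: HubProfile,
    top_k: int | None = None,
    threshold: float | None = None,
) -> list[str]:
    """Hub call: the ``top_k`` nodes, or all nodes with average degree >=
    ``threshold``, in descending average degree (alphabetical tie-break).

    Exactly one selector must be given.
    """
    if (top_k is None) == (threshold is None):
        raise ValueError("give exactly one of top_k or threshold")
    ranked = profile.ranking
    if top_k is not None:
        return ranked[:top_k]
    return [v for v in ranked if profile.avg_degree[v] >= threshold]


def write_profile_tsv(profile: HubProfile, path) -> None:
    """``node<TAB>avg_degree<TAB>rank`` rows, in rank order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tavg_degree\trank\n")
        for rank, v in enumerate(profile.ranking, start=1):
            fh.write(f"{v}\t{profile.avg_degree[v]:.6g}\t{rank}\n")


def plot_profile(profile: HubProfile, path) -> None:
    """Bar chart of average degrees (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = profile.ranking
    values = [profile.avg_degree[v] for v in ranked]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(ranked)), 3))
    ax.bar(range(len(ranked)), values)
    ax.set_xticks(range(len(ranked)))
    ax.set_xticklabels(ranked, rotation=90, fontsize=7)
    ax.set_ylabel("average tree degree")
    ax.set_title(f"hub profile over {profile.archive_size} optimal trees")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
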