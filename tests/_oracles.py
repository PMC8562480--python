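"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written in the most literal way possible (double loops, direct
formula transcription) and using dendropy's own patristic distances, so they
share no code path with the package internals they check.
"""
import numpy as np

from gutassembly.containers import OtuTable, PhyloTree


def dendropy_patristic(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Patristic distances via dendropy's PhylogeneticDistanceMatrix."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    labels = list(tree.tip_labels)
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return labels, out


def brute_beta_mntd(table: OtuTable, tree: PhyloTree,
                    weighted: bool) -> np.ndarray:
    """Literal double-loop transcription of the beta-MNTD formula."""
    labels, dist = dendropy_patristic(tree)
    col = {lab: i for i, lab in enumerate(labels)}
    counts = table.counts
    otus = table.otu_ids
    n = table.n_samples
    out = np.zeros((n, n))

    def one_direction(a: int, b: int) -> float:
        present_a = [o for o, c in zip(otus, counts[a]) if c > 0]
        present_b = [o for o, c in zip(otus, counts[b]) if c > 0]
        total_a = sum(c for c in counts[a] if c > 0)
        acc = 0.0
        for o, c in zip(otus, counts[a]):
            if c <= 0:
                continue
            nearest = min(dist[col[o], col[q]] for q in present_b)
            f = c / total_a if weighted else 1.0 / len(present_a)
            acc += f * nearest
        return acc

    for k in range(n):
        for m in range(k + 1, n):
            val = 0.5 * (one_direction(k, m) + one_direction(m, k))
            out[k, m] = out[m, k] = val
    return out


def brute_mantel_r(sq1: np.ndarray, sq2: np.ndarray) -> float:
    """Pearson r over all off-diagonal pairs via an explicit loop."""
    xs, ys = [], []
    n = sq1.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            xs.append(sq1[i, j])
            ys.append(sq2[i, j])
    xs = np.array(xs)
    ys = np.array(ys)
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
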