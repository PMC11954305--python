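"""Independent reference implementations used as test oracles.

These are deliberately written with plain loops and explicit data
structures, separate from the package's implementations, so equivalence
tests compare two genuinely independent derivations.
"""

from insynth.chem import tanimoto


def reference_butina(fps, cutoff):
    """O(n^2) Butina sphere exclusion over an explicit distance matrix.

    Returns [(centroid, sorted_members), ...] ordered by descending size,
    ties by discovery order; centroid ties break toward the lowest index.
    """
    n = len(fps)
    dist = [[1.0 - tanimoto(fps[i], fps[j]) for j in range(n)] for i in range(n)]
    neighbors = [{j for j in range(n) if dist[i][j] <= cutoff} for i in range(n)]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best, best_count = None, -1
        for i in sorted(unassigned):
            count = len(neighbors[i] & unassigned)
            if count > best_count:  # ties break toward the lowest index
                best, best_count = i, count
        members = sorted(neighbors[best] & unassigned)
        clusters.append((best, members))
        unassigned -= set(members)
    order = sorted(range(len(clusters)), key=lambda k: (-len(clusters[k][1]), k))
    return [clusters[k] for k in order]


def reference_pareto(values):
    """O(n^2) non-domination check (maximization) with plain loops."""
    n = len(values)
    d = len(values[0]) if n else 0
    front = []
    for i in range(n):
        dominated = False
        for j in range(n):
            if j == i:
                continue
            ge = all(values[j][k] >= values[i][k] for k in range(d))
            gt = any(values[j][k] > values[i][k] for k in range(d))
            if ge and gt:
                dominated = True
                break
        if not dominated:
            front.append(i)
    return front
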