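"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — O(n^2) pair scans, positional
base counting, exhaustive alignment enumeration — and shares no code with
the implementation paths it checks.
"""

from __future__ import annotations

from collections import deque


def positional_gap(a_start, a_end, b_start, b_end) -> int:
    """Count integer positions strictly between two half-open intervals by
    literally enumerating them."""
    lo = min(a_end, b_end)
    hi = max(a_start, b_start)
    return len([p for p in range(lo, hi)])


def brute_force_components(
    predictions,
    alignments,
    vicinity_bp: int = 50,
    min_cover_bp: int = 1,
    transcript_vicinity_rule: bool = True,
):
    """Connected components of the fusion rules by O(n^2) edge enumeration
    and BFS flood fill. Nodes are ("pred", id) / ("tx", id) tuples; returns
    a set of frozensets."""

    def gap(x, y):
        if x.scaffold_id != y.scaffold_id:
            return None
        return max(0, max(x.span.start, y.span.start) - min(x.span.end, y.span.end))

    def overlap_len(iv, span):
        if iv.scaffold_id != span.scaffold_id:
            return 0
        return max(0, min(iv.end, span.end) - max(iv.start, span.start))

    nodes = [("pred", p.gene_id) for p in predictions] + [
        ("tx", a.transcript_id) for a in alignments
    ]
    adj = {n: set() for n in nodes}

    def connect(u, v):
        adj[u].add(v)
        adj[v].add(u)

    covered = set()
    for a in alignments:
        for p in predictions:
            if any(overlap_len(b, p.span) >= min_cover_bp for b in a.blocks):
                connect(("tx", a.transcript_id), ("pred", p.gene_id))
                covered.add(p.gene_id)
    for i, a in enumerate(alignments):
        for b in alignments[i + 1 :]:
            g = gap(a, b)
            if g == 0 and a.span.overlaps(b.span):
                connect(("tx", a.transcript_id), ("tx", b.transcript_id))
    for i, p in enumerate(predictions):
        for q in predictions[i + 1 :]:
            g = gap(p, q)
            if g is not None and g < vicinity_bp and (
                p.gene_id in covered or q.gene_id in covered
            ):
                connect(("pred", p.gene_id), ("pred", q.gene_id))
    if transcript_vicinity_rule:
        for p in predictions:
            for a in alignments:
                g = gap(p, a)
                if g is not None and 0 < g < vicinity_bp:
                    connect(("pred", p.gene_id), ("tx", a.transcript_id))

    seen = set()
    components = set()
    for start in nodes:
        if start in seen:
            continue
        comp = set()
        queue = deque([start])
        while queue:
            n = queue.popleft()
            if n in comp:
                continue
            comp.add(n)
            queue.extend(adj[n] - comp)
        seen |= comp
        components.add(frozenset(comp))
    return components


def enumerate_global_alignments(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Exhaustively enumerate every global alignment of two tiny sequences;
    return (best score, set of identity fractions among best-scoring
    alignments), with N matching nothing."""
    best = {"score": None}
    results = []

    def rec(i, j, score, matches, cols):
        if i == len(a) and j == len(b):
            results.append((score, matches, cols))
            return
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] != "N") else mismatch
            rec(i + 1, j + 1, score + s, matches + (1 if s == match else 0), cols + 1)
        if i < len(a):
            rec(i + 1, j, score + gap, matches, cols + 1)
        if j < len(b):
            rec(i, j + 1, score + gap, matches, cols + 1)

    rec(0, 0, 0.0, 0, 0)
    best_score = max(s for s, _, _ in results)
    identities = {m / c for s, m, c in results if s == best_score}
    return best_score, identities


def greedy_cluster_reference(transcripts, threshold, identity_fn):
    """Straight-line reimplementation of greedy centroid clustering with no
    prefilters: longest-first (ties on id), join the first cluster whose
    representative reaches the threshold."""
    order = sorted(transcripts, key=lambda kv: (-len(kv[1]), kv[0]))
    clusters = []  # (rep_id, rep_seq, [member_ids])
    for tid, seq in order:
        for cl in clusters:
            if identity_fn(seq, cl[1]) >= threshold:
                cl[2].append(tid)
                break
        else:
            clusters.append((tid, seq, [tid]))
    return {frozenset(members) for _, _, members in clusters}


def random_fusion_instance(rng, max_preds=40, max_txs=25, n_scaffolds=2, coord_max=3000):
    """A random fusion-graph instance: predictions with 1-2 exons and
    transcripts with 1-3 blocks scattered over a few short scaffolds."""
    from locusfuse.model import GenePrediction, GenomicInterval, TranscriptAlignment

    preds = []
    for i in range(int(rng.integers(1, max_preds + 1))):
        scaf = f"s{int(rng.integers(0, n_scaffolds))}"
        start = int(rng.integers(0, coord_max))
        exons = []
        pos = start
        for _ in range(int(rng.integers(1, 3))):
            length = int(rng.integers(10, 120))
            exons.append(GenomicInterval(scaf, pos, pos + length))
            pos += length + int(rng.integers(20, 200))
        preds.append(GenePrediction(gene_id=f"p{i}", exons=exons))
    txs = []
    for i in range(int(rng.integers(0, max_txs + 1))):
        scaf = f"s{int(rng.integers(0, n_scaffolds))}"
        pos = int(rng.integers(0, coord_max))
        blocks = []
        for _ in range(int(rng.integers(1, 4))):
            length = int(rng.integers(10, 150))
            blocks.append(GenomicInterval(scaf, pos, pos + length))
            pos += length + int(rng.integers(25, 300))
        total = sum(b.length for b in blocks)
        txs.append(
            TranscriptAlignment(
                transcript_id=f"t{i}",
                scaffold_id=scaf,
                blocks=blocks,
                query_length=total,
                matches=total,
            )
        )
    return preds, txs
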