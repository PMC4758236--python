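"""Reference-transcriptome construction by greedy centroid clustering.

Raw transcripts are collapsed into clusters at a global-identity threshold;
each cluster is represented by its longest member. Transcripts are
processed in descending length order (ties broken by ascending id), so the
representative of every cluster is its founder. This emulates the usual
centroid-clustering behaviour of transcript-collapse tools.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_IDENTITY_THRESHOLD = 0.97
_ALPHABET = "ACGTN"


@dataclass
class TranscriptCluster:
    representative_id: str
    member_ids: list[str]
    representative_length: int

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError(
                f"representative {self.representative_id} is not a member of its cluster"
            )


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    # N must match nothing, including another N, so a plain match/mismatch
    # score pair is not enough: build an explicit 5x5 substitution matrix.
    mat = substitution_matrices.Array(_ALPHABET, dims=2)
    for x in _ALPHABET:
        for y in _ALPHABET:
            mat[x, y] = match if (x == y and x != "N") else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"empty sequence: {label}")
    if set(seq) - set(_ALPHABET):
        raise ValueError(
            f"{label}: alphabet must be uppercase {_ALPHABET}, "
            f"found {sorted(set(seq) - set(_ALPHABET))}"
        )


def pairwise_identity(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Global-alignment identity: matches / alignment columns, in [0, 1].

    The two sequences are globally aligned (Needleman-Wunsch, linear gap
    penalty); identity is the fraction of alignment columns where both rows
    carry the same base, with N matching nothing. The argument order is
    canonicalized before aligning, so identity(a, b) == identity(b, a)
    exactly even when co-optimal alignments differ in match count.
    """
    _check_sequence(a, "first sequence")
    _check_sequence(b, "second sequence")
    if (len(a), a) > (len(b), b):
        a, b = b, a
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x != "-" and x != "N"
    )
    return matches / len(row_a)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(
    transcripts: list[tuple[str, str]],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    prefilter_kmer: int = 12,
) -> list[TranscriptCluster]:
    """Greedy centroid clustering at a global-identity threshold.

    Transcripts are processed longest-first (ties on ascending id); each
    joins the first existing cluster whose representative aligns at
    identity >= threshold, otherwise it founds a new cluster. Two cheap
    guards skip hopeless alignments without changing the result:

    * length ratio — identity <= min(len)/max(len) for any global
      alignment, so pairs below the threshold ratio cannot pass;
    * shared k-mer — applied only when threshold >= 0.95 and both
      sequences are at least 2k long, where an identity >= threshold
      alignment forces a conserved k-mer.

    Output clusters are sorted by representative_id.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ids = [tid for tid, _ in transcripts]
    if len(ids) != len(set(ids)):
        dup = sorted({t for t in ids if ids.count(t) > 1})
        raise ValueError(f"duplicate transcript ids: {dup[:5]}")
    for tid, seq in transcripts:
        _check_sequence(seq, tid)

    order = sorted(transcripts, key=lambda kv: (-len(kv[1]), kv[0]))
    use_kmer = threshold >= 0.95
    clusters: list[dict] = []  # creation order; {"rep_id", "rep_seq", "kmers", "members"}
    for tid, seq in order:
        kmers = _kmer_set(seq, prefilter_kmer) if use_kmer else None
        joined = False
        for cl in clusters:
            rep = cl["rep_seq"]
            if len(seq) < threshold * len(rep):  # rep is >= len(seq) by order
                continue
            if (
                use_kmer
                and len(seq) >= 2 * prefilter_kmer
                and len(rep) >= 2 * prefilter_kmer
                and kmers.isdisjoint(cl["kmers"])
            ):
                continue
            if pairwise_identity(seq, rep) >= threshold:
                cl["members"].append(tid)
                joined = True
                break
        if not joined:
            clusters.append(
                {
                    "rep_id": tid,
                    "rep_seq": seq,
                    "kmers": kmers if use_kmer else None,
                    "members": [tid],
                }
            )
    out = [
        TranscriptCluster(
            representative_id=cl["rep_id"],
            member_ids=cl["members"],
            representative_length=len(cl["rep_seq"]),
        )
        for cl in clusters
    ]
    out.sort(key=lambda c: c.representative_id)
    return out


def reference_transcriptome(
    clusters: list[TranscriptCluster], transcripts: dict[str, str]
) -> dict[str, str]:
    """The reference transcriptome: one record per cluster, the longest
    member's sequence under the representative's id."""
    out: dict[str, str] = {}
    for cl in clusters:
        if cl.representative_id not in transcripts:
            raise KeyError(
                f"representative {cl.representative_id} missing from sequence map"
            )
        out[cl.representative_id] = transcripts[cl.representative_id]
    return out


def write_clusters_tsv(clusters: list[TranscriptCluster], path: str | os.PathLike) -> None:
    rows = [
        {
            "cluster_id": f"cl_{i:06d}",
            "member_id": member,
            "is_representative": int(member == cl.representative_id),
        }
        for i, cl in enumerate(clusters)
        for member in cl.member_ids
    ]
    pd.DataFrame(rows, columns=["cluster_id", "member_id", "is_representative"]).to_csv(
        path, sep="\t", index=False
    )


def mean_length(transcripts: dict[str, str]) -> float:
    if not transcripts:
        return float("nan")
    return float(np.mean([len(s) for s in transcripts.values()]))
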