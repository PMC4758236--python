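from __future__ import annotations

from pathlib import Path

import pytest

from locusfuse import cluster as cl
from locusfuse import io_formats as iof
from locusfuse import loci as lb
from locusfuse.synthetic import SimulationParams, TruthTable, generate


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory) -> tuple[Path, TruthTable, SimulationParams]:
    """A moderate-noise synthetic dataset under the generator defaults."""
    outdir = tmp_path_factory.mktemp("sim_default")
    params = SimulationParams(n_true_loci=60, seed=11)
    truth = generate(params, outdir, overwrite=True)
    return outdir, truth, params


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory) -> tuple[Path, TruthTable, SimulationParams]:
    """Zero-noise limit: no splitting, full support, one exact transcript
    per locus — the regime where consolidation must recover truth exactly."""
    outdir = tmp_path_factory.mktemp("sim_clean")
    params = SimulationParams(
        n_true_loci=40,
        seed=5,
        prediction_split_rate=0.0,
        scaffold_split_rate=0.0,
        transcript_support_fraction=1.0,
        redundancy=1.0,
        divergence=0.0,
    )
    truth = generate(params, outdir, overwrite=True)
    return outdir, truth, params


def consolidate(dataset_dir: Path, cluster_identity: float = 0.97, **loci_kwargs):
    """Run cluster -> filter alignments -> build loci from a dataset dir;
    returns (predictions, alignments, loci, representative_ids)."""
    predictions = iof.read_gff3(dataset_dir / "predictions.gff3")
    alignments = iof.read_psl(dataset_dir / "alignments.psl")
    seqs = iof.read_fasta(dataset_dir / "transcripts.fasta")
    clusters = cl.greedy_cluster(list(seqs.items()), threshold=cluster_identity)
    reps = set(cl.reference_transcriptome(clusters, seqs))
    alignments = [a for a in alignments if a.transcript_id in reps]
    loci = lb.build_loci(predictions, alignments, **loci_kwargs)
    return predictions, alignments, loci, reps


@pytest.fixture(scope="session")
def default_consolidation(default_dataset):
    outdir, truth, params = default_dataset
    return consolidate(outdir)


@pytest.fixture(scope="session")
def clean_consolidation(clean_dataset):
    outdir, truth, params = clean_dataset
    return consolidate(outdir)
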