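"""Shared fixtures: packaged codon tables and a toy splice atlas."""

from __future__ import annotations

import pytest

from hskit import codon_usage as cu
from hskit import fixtures as fx
from hskit import splice_atlas as sa


@pytest.fixture(scope="session")
def moss_table():
    return cu.load_species_table("physcomitrium_patens")


@pytest.fixture(scope="session")
def moss_map(moss_table):
    return cu.derive_substitution_map(moss_table)


@pytest.fixture(scope="session")
def toy_atlas(tmp_path_factory):
    """Toy genome + annotation profiled end to end.

    Returns a dict with the genome mapping, transcript models, extracted
    windows, donor/acceptor PFMs and the generator's ground truth.
    """
    genome, gff3, truth = fx.make_toy_genome(
        n_genes=40, introns_per_gene=3, donor_caggt_fraction=0.23, seed=7
    )
    gff_path = tmp_path_factory.mktemp("toy") / "toy.gff3"
    gff_path.write_text(gff3)
    models = sa.load_transcript_models(gff_path, genome)
    windows = sa.extract_splice_windows(models, genome)
    donors = [w for w in windows if w.kind == "donor"]
    acceptors = [w for w in windows if w.kind == "acceptor"]
    return {
        "genome": genome,
        "gff3": gff3,
        "gff_path": gff_path,
        "truth": truth,
        "models": models,
        "windows": windows,
        "donor_pfm": sa.build_pfm(donors),
        "acceptor_pfm": sa.build_pfm(acceptors),
    }
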