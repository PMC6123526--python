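"""Shared fixtures: a small synthetic dataset with planted truth."""

import pytest

import rnannotate as rn


@pytest.fixture(scope="session")
def small_dataset():
    """20 kb genome, 8 operons, 4 sRNAs, 2 sORFs; deterministic."""
    return rn.simulate_dataset(
        length=20_000, n_operons=8, polycistronic_fraction=0.5,
        n_srnas=4, n_sorfs=2, seed=1,
    )


@pytest.fixture(scope="session")
def small_tracks(small_dataset):
    ds = small_dataset
    tracks = rn.simulate_coverage(
        ds.genome, ds.truth, rn.default_libraries(), depth=50.0, noise_sd=5.0, seed=1
    )
    return rn.normalize_tracks(tracks)


@pytest.fixture(scope="session")
def tex_pairs(small_tracks):
    tex_plus = [t for t in small_tracks if t.library.treatment == "TEX_plus"]
    tex_minus = [t for t in small_tracks if t.library.treatment == "TEX_minus"]
    return tex_plus, tex_minus


@pytest.fixture(scope="session")
def called_transcripts(small_dataset, small_tracks):
    return rn.merge_with_genes(rn.call_transcripts(small_tracks), small_dataset.genes)


@pytest.fixture(scope="session")
def called_tss(small_dataset, tex_pairs):
    tex_plus, tex_minus = tex_pairs
    sites = rn.call_sites(tex_plus, tex_minus, rn.ParamSet(), mode="TSS")
    return rn.classify_tss(sites, small_dataset.genes)


@pytest.fixture(scope="session")
def called_ps(tex_pairs):
    tex_plus, tex_minus = tex_pairs
    return rn.call_sites(tex_plus, tex_minus, rn.ParamSet(), mode="PS")
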