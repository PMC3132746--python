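import numpy as np
import pytest

from ricedge import mapping, simulate, tags


@pytest.fixture(scope="session")
def small_config():
    return simulate.SyntheticConfig(
        n_genes=120, depth=20_000, error_rate=0.0, effect_log2=1.5, seed=5
    )


@pytest.fixture(scope="session")
def small_trio(small_config):
    """A noise-free synthetic trio, mapped end to end (shared across tests)."""
    cfg = small_config
    transcripts = simulate.generate_transcriptome(cfg)
    truth = simulate.generate_expression_profiles(cfg)
    index, untaggable = tags.index_transcripts(transcripts)
    mapped = {}
    for name, ab, sub in (("p1", truth.p1, 11), ("p2", truth.p2, 12), ("f1", truth.f1, 13)):
        lib = simulate.sample_tag_library(
            transcripts, ab, cfg.depth, cfg.error_rate, seed=cfg.seed * 1000 + sub
        )
        observed = mapping.ObservedTagSet(name, dict(zip(lib["tag"], lib["count"])))
        mapped[name], _ = mapping.map_tags(observed, index)
    return {
        "config": cfg,
        "transcripts": transcripts,
        "truth": truth,
        "index": index,
        "untaggable": untaggable,
        "mapped": mapped,
    }


def trio_counts_from_truth(cfg, truth, seed):
    """Multinomial tag counts drawn directly from the truth abundances."""
    rng = np.random.default_rng(seed)
    genes = truth.table["gene_id"].to_numpy()

    def mk(name, abundance):
        counts = rng.multinomial(cfg.depth, abundance)
        return mapping.MappedCounts(
            name, dict(zip(genes, (int(v) for v in counts))), cfg.depth
        )

    return mk("p1", truth.p1), mk("p2", truth.p2), mk("f1", truth.f1)
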