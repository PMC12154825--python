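import numpy as np
import pytest

import colormove as cm


def random_text(rng, n_docs=3, min_len=5, max_len=120):
    """A random multi-document collection plus its concatenated text."""
    docs = []
    for d in range(n_docs):
        n_seqs = int(rng.integers(1, 3))
        seqs = [
            "".join(rng.choice(list("ACGT"), int(rng.integers(min_len, max_len))))
            for _ in range(n_seqs)
        ]
        docs.append(cm.Document(d, f"D{d}", seqs))
    return cm.DocumentCollection(docs, {d: 100 + d for d in range(n_docs)})


@pytest.fixture(scope="session")
def worked():
    """The hand-worked two-document fixture: D1="ACA", D2="ACG"."""
    coll = cm.DocumentCollection(
        [cm.Document(0, "D1", ["ACA"]), cm.Document(1, "D2", ["ACG"])],
        {0: 100, 1: 101},
    )
    text = cm.build_concat(coll)
    st = cm.build_suffix_structures(text)
    runs = cm.find_runs(st.bwt_codes)
    th = cm.compute_thresholds(runs, st)
    table = cm.build_move_table(runs, st, th)
    run_colors = cm.compute_run_colors(runs, st)
    colors = cm.build_color_table(run_colors, n_docs=2)
    cm.assign_colors(table, colors)
    return {
        "collection": coll, "text": text, "structures": st, "runs": runs,
        "thresholds": th, "table": table, "run_colors": run_colors,
        "colors": colors,
    }


@pytest.fixture(scope="session")
def small_pangenome():
    """5 species x 3 genomes x 10 kb, easy settings for recovery tests."""
    params = cm.PangenomeSimParams(
        n_species=5, genomes_per_species=3, genome_length=10_000,
        inter_species_divergence=0.10, intra_species_divergence=0.01, seed=42,
    )
    collection, tree, held_out = cm.simulate_pangenome(params)
    bundle = cm.build_index(collection, taxonomy=tree)
    return {
        "params": params, "collection": collection, "tree": tree,
        "held_out": held_out, "bundle": bundle,
    }


def build_table_for(S, boundaries=None):
    """Index a raw terminated string (optionally multi-document)."""
    if boundaries is None:
        boundaries = [(0, len(S) - 1)]
    text = cm.ConcatText(S, boundaries)
    st = cm.build_suffix_structures(text)
    runs = cm.find_runs(st.bwt_codes)
    th = cm.compute_thresholds(runs, st)
    table = cm.build_move_table(runs, st, th)
    colors = cm.build_color_table(cm.compute_run_colors(runs, st),
                                  n_docs=len(boundaries))
    cm.assign_colors(table, colors)
    return st, runs, table, colors
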