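import pytest

from foldnet import synthetic

SMALL_KW = dict(
    n_genes=300,
    n_probes=345,
    planted_down={"kd1": (30, 0.25), "kd2": (20, 0.3)},
    planted_up={"kd1": (10, 4.0), "kd2": (8, 4.0)},
    n_common_down=8,
    planted_module_size=12,
    category_size_range=(5, 30),
    noise_sd=0.0,
    seed=42,
)


@pytest.fixture(scope="session")
def small_design():
    """Small zero-noise design usable by every stage."""
    return synthetic.SyntheticDesign(**SMALL_KW)


@pytest.fixture(scope="session")
def small_data(small_design):
    table, probe_map, truth = synthetic.generate_expression(small_design)
    return {
        "design": small_design,
        "table": table,
        "probe_map": probe_map,
        "truth": truth,
        "graph": synthetic.generate_ppi(small_design),
        "go": synthetic.generate_catalog(small_design, "go_like"),
        "kegg": synthetic.generate_catalog(small_design, "kegg_like"),
    }
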