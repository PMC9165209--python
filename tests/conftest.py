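import pytest

from oa_crust_meta import SyntheticConfig, compute_effect_sizes, generate_with_truth
from oa_crust_meta.pipeline import derive_missing_pco2


@pytest.fixture(scope="session")
def default_dataset():
    """Synthetic extraction dataset under the reference study conditions."""
    return generate_with_truth(SyntheticConfig(rng_seed=20260923))


@pytest.fixture(scope="session")
def default_effects(default_dataset):
    records, _ = default_dataset
    records, _ = derive_missing_pco2(records)
    return compute_effect_sizes(records)


@pytest.fixture()
def record_kwargs():
    """Baseline keyword arguments for a valid StudyRecord."""
    return dict(
        record_id="r1",
        article_id="a1",
        species="Carcinus maenas",
        order="Decapoda",
        life_stage="adult",
        latitude_deg=54.0,
        anatomy="carapace",
        parameter="calcium",
        unit="percent_dry_mass",
        mean_control=20.0,
        mean_treatment=18.0,
        var_stat_control=2.0,
        var_stat_treatment=2.2,
        var_type="SD",
        n_control=6,
        n_treatment=6,
        pco2_treatment_uatm=1600.0,
    )
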