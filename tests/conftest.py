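import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from scipy.special import ndtri

from pfsskit import io as tbl
from pfsskit.synthetic import GroupSpec, SyntheticSpec, generate_campaign


@pytest.fixture
def worked_example(tmp_path):
    """One-domain campaign reproducing the README worked example.

    Two included reference sites of the PP2C aspartate-OD2 model give a
    gamma of (0.9935 + 0.9515)/2 = 0.9725; the single model-side site at
    residue 1003 sits 0.0493 below the reference probability, so its PFSS is
    (1 - 0.0493)/0.9725 = 0.9776 at 4 decimals.
    """
    model_id = "PP2C.6.ASP.OD2"
    paths = {
        "calibration": tmp_path / "calibration.tsv",
        "ref_sites": tmp_path / "reference_sites.tsv",
        "model_sites": tmp_path / "model_sites.tsv",
        "domains": tmp_path / "domains.tsv",
    }
    tbl.write_calibration_table(
        [tbl.CalibrationEntry(model_id, 0.0, 1.0, 1.0)], paths["calibration"])
    tbl.write_site_table([
        tbl.SitePrediction("T1169", model_id, "A", 1003, "OD2", float(ndtri(0.9935))),
        tbl.SitePrediction("T1169", model_id, "A", 1010, "OD2", float(ndtri(0.9515))),
    ], paths["ref_sites"])
    tbl.write_site_table([
        tbl.SitePrediction("T1169/Yang_Server/1", model_id, "A", 1003, "OD2",
                           float(ndtri(0.9935 - 0.0493))),
    ], paths["model_sites"])
    tbl.write_domain_table(
        [tbl.DomainDefinition("T1169", "T1169-D4", ((1000, 1100),), "FM")],
        paths["domains"])
    return paths


@pytest.fixture(scope="session")
def small_campaign():
    """A small seeded campaign: 8 domains, 5 SeqFEATURE models, 4 groups
    spanning zero to severe error, one with partial coverage."""
    spec = SyntheticSpec(
        n_sf_models=5, n_targets=4, domains_per_target=2, sites_per_domain=4.0,
        groups=(
            GroupSpec("exact", 0.0, 1.0),
            GroupSpec("good", 0.2, 1.0),
            GroupSpec("noisy", 1.0, 1.0),
            GroupSpec("partial", 0.5, 0.6),
        ),
        seed=42,
    )
    return generate_campaign(spec)
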