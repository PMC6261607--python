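import pytest

from fibroscreen import hca, synth


@pytest.fixture(scope="session")
def hca_layout():
    return synth.generate_plate_layout(16, 24, synth.hca_design())


@pytest.fixture(scope="session")
def control_fields(hca_layout):
    """A dozen control wells (6 per role) at moderate density: shared by the
    segmentation, feature and classifier tests."""
    ctrl = hca_layout.wells[
        hca_layout.wells["role"].isin(["neg_control", "pos_control"])
    ]["well"]
    return synth.simulate_hca_plate(
        hca_layout, seed=42, n_cells_per_well=60, wells=list(ctrl)[:12]
    )


@pytest.fixture(scope="session")
def control_features(control_fields):
    return hca.extract_plate_features(control_fields, attach_truth_labels=True)
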