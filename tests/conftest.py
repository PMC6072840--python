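import pytest

from epitopepred import build_ensemble, generate_synthetic_dataset

#: single-combination grids so fixture training stays fast
FAST_GRIDS = {
    "ERT": {"n_estimators": [50]},
    "GB": {"n_estimators": [50], "learning_rate": [0.1]},
}


@pytest.fixture(scope="session")
def synthetic_sets():
    """Strongly separated positive/negative peptides (100 per class)."""
    peptides = generate_synthetic_dataset(100, 100, bias_strength=5.0, seed=11)
    pos = [p for p in peptides if p.label == 1]
    neg = [p for p in peptides if p.label == 0]
    return pos, neg


@pytest.fixture(scope="session")
def small_ensemble():
    """A small but functional EM1 ensemble trained on synthetic peptides."""
    peptides = generate_synthetic_dataset(80, 80, bias_strength=5.0, seed=23)
    model, report = build_ensemble(
        peptides, seed=23, folds=3, repeats=1, grids=FAST_GRIDS
    )
    return model, report
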