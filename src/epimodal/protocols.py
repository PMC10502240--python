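"""Desk-scale benchmark protocols.

The published results (epigenetic-profile AUPRC tables, disparity-test
significance frequencies, zero-/few-shot pathogenicity curves) come from
genome-scale data and GPU-scale training.  This module fixes the package's
desk-scale analogues of those experiments — synthetic study conditions,
miniature model configurations and training protocols — in one place, so
the test suite, the acceptance script and the examples all run the exact
same experiments.

Protocols (all deterministic given their seed):

``profile_prediction_run``  train a miniature multimodal model and its
    sequence-only ablation on a default fixture with chromosome-held-out
    splits and compare macro-AUPRC on the structure-driven events — the
    direction-of-effect analogue of the published sequence-vs-multimodal
    comparison.
``disparity_power_run``     generate a larger fixture (the disparity test
    draws only 2% of samples, so it needs more windows than model training
    does) and run the rank-sum disparity test.
``variant_effect_run``      pretrain a miniature encoder on a motif-dense
    fixture, then score held-out synthetic variants zero-shot and few-shot
    with the Siamese classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disparity import run_disparity_test
from .encoders import (
    MultimodalModel,
    SequenceEncoderConfig,
    StructureEncoderConfig,
    build_sequence_encoder,
    build_structure_encoder,
)
from .genome_io import apply_variant
from .synthetic import Fixture, SyntheticConfig, generate_fixture
from .training import TrainConfig, WindowDataset, auprc, evaluate, train
from .variant_effects import VariantBatch, fit_siamese, zero_shot_scores

# training-fixture conditions: the default synthetic config (4 x 20-kb
# chromosomes, 1-kb windows, 5-kb Hi-C bins, 24 events, beta = 0.5)
TRAIN_FIXTURE = SyntheticConfig()

# the disparity test draws 2% of samples; a larger genome keeps the drawn
# pair set big enough for the rank-sum comparisons to have power
DISPARITY_FIXTURE = SyntheticConfig(n_chroms=6, chrom_length=40_000)

# variant-effect fixture: shorter (400-bp) neighbourhoods and longer
# chromosomes give the miniature encoder enough windows to learn the
# planted motifs, which zero-shot scoring depends on
VARIANT_FIXTURE = SyntheticConfig(chrom_length=100_000, window_length=400,
                                  n_variants=900)

TRAIN_CHROMS = ("chr1", "chr2")
VALID_CHROM = "chr3"
TEST_CHROM = "chr4"

# miniature training protocols
PROFILE_TRAIN = dict(learning_rate=3e-3, max_epochs=25, patience=4,
                     batch_size=64)
# motif learning has a long optimisation plateau; the variant-effect
# pretraining rides it out (best-validation checkpoint is still returned)
VARIANT_PRETRAIN = dict(learning_rate=3e-3, max_epochs=60, patience=60,
                        batch_size=64)
SIAMESE_FIT = dict(learning_rate=1e-3, max_epochs=40, patience=8)

FEWSHOT_TRAIN_SIZE = 400
FEWSHOT_VALID_SIZE = 100


def chromosome_split(fixture: Fixture) -> tuple[WindowDataset, WindowDataset, WindowDataset]:
    """Chromosome-held-out train/valid/test datasets."""
    chroms = fixture.sample_chroms()
    data = WindowDataset(fixture.onehot, fixture.sample_hic_bins, fixture.labels)
    return (
        data.subset(np.isin(chroms, TRAIN_CHROMS)),
        data.subset(chroms == VALID_CHROM),
        data.subset(chroms == TEST_CHROM),
    )


def build_miniature(fixture: Fixture, seed: int, structure: str | None = "mlp",
                    ) -> MultimodalModel:
    """Miniature multimodal model (or sequence-only ablation) for a fixture."""
    seq = build_sequence_encoder(
        SequenceEncoderConfig.miniature("cnn", window_length=fixture.config.window_length),
        seed=seed,
    )
    struct = None
    if structure is not None:
        struct = build_structure_encoder(
            StructureEncoderConfig.miniature(structure), fixture.matrix, seed=seed + 1
        )
    return MultimodalModel(seq, struct, n_events=fixture.config.n_events,
                           rng=np.random.default_rng(seed + 2))


@dataclass
class ProfileRunResult:
    multimodal_struct_auprc: float
    seqonly_struct_auprc: float

    @property
    def improvement(self) -> float:
        return self.multimodal_struct_auprc - self.seqonly_struct_auprc


def profile_prediction_run(seed: int) -> ProfileRunResult:
    """Train multimodal vs sequence-only miniatures; compare macro-AUPRC on
    the structure-driven events of the held-out chromosome."""
    fixture = generate_fixture(SyntheticConfig(**{**_cfgdict(TRAIN_FIXTURE), "seed": seed}))
    tr, va, te = chromosome_split(fixture)
    struct_events = fixture.structure_events()
    scores = {}
    for name, structure in (("multimodal", "mlp"), ("seqonly", None)):
        model = build_miniature(fixture, seed, structure)
        model, _ = train(model, tr, va, TrainConfig(seed=seed, **PROFILE_TRAIN))
        report = evaluate(model, te)
        scores[name] = float(np.nanmean(report.auprc_per_event[struct_events]))
    return ProfileRunResult(scores["multimodal"], scores["seqonly"])


def disparity_power_run(seed: int, beta: float, frac: float = 0.02,
                        repeats: int = 3, margin: float = 10.0) -> list[float]:
    """Under-comparison p-values of the disparity test on one fixture."""
    cfg = SyntheticConfig(**{**_cfgdict(DISPARITY_FIXTURE),
                             "seed": seed, "structure_beta": beta})
    fx = generate_fixture(cfg)
    report = run_disparity_test(fx.sequences, fx.labels, fx.sample_hic_bins,
                                fx.matrix, frac=frac, repeats=repeats,
                                margin=margin, seed=seed)
    return report.under_p


def variant_batch(fixture: Fixture) -> VariantBatch:
    """Ref/alt windows and effect labels for a fixture's variants."""
    ref, alt, bins_, labels = [], [], [], []
    wl = fixture.config.window_length
    for v in fixture.variants:
        rw, aw = apply_variant(fixture.assembly, v.record, wl)
        ref.append(rw.onehot)
        alt.append(aw.onehot)
        bins_.append(fixture.grid.bin_of(v.record.chrom, v.record.pos))
        labels.append(int(v.is_effect))
    return VariantBatch(np.stack(ref), np.stack(alt), np.asarray(bins_),
                        np.asarray(labels))


@dataclass
class VariantRunResult:
    zero_shot_auprc: float
    few_shot_auprc: float
    n_test: int


def variant_effect_run(seed: int) -> VariantRunResult:
    """Zero-shot vs 400-variant few-shot pathogenicity on one fixture."""
    cfg = SyntheticConfig(**{**_cfgdict(VARIANT_FIXTURE), "seed": seed})
    fixture = generate_fixture(cfg)
    tr, va, _ = chromosome_split(fixture)
    model = build_miniature(fixture, seed, "mlp")
    model, _ = train(model, tr, va, TrainConfig(seed=seed, **VARIANT_PRETRAIN))
    batch = variant_batch(fixture)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(batch))
    n_tr, n_va = FEWSHOT_TRAIN_SIZE, FEWSHOT_VALID_SIZE
    train_b = batch.subset(order[:n_tr])
    valid_b = batch.subset(order[n_tr : n_tr + n_va])
    test_b = batch.subset(order[n_tr + n_va :])
    zs = zero_shot_scores(model, test_b)
    clf = fit_siamese(model, train_b, valid_b, seed=seed, **SIAMESE_FIT)
    fs = clf.predict(test_b.ref_onehot, test_b.alt_onehot, test_b.bins)
    return VariantRunResult(
        zero_shot_auprc=auprc(zs, test_b.labels),
        few_shot_auprc=auprc(fs, test_b.labels),
        n_test=len(test_b),
    )


def _cfgdict(cfg: SyntheticConfig) -> dict:
    import dataclasses

    return dataclasses.asdict(cfg)
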