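"""cicnet: multi-task autoencoders for transcriptome cell identity codes.

Compresses whole-transcriptome mRNA expression profiles into a
low-dimensional cell identity code (CIC) and decodes it into the
reconstructed mRNA profile, a predicted miRNA profile, a tissue-of-origin
class and a disease-state class, with contractive or variational
regularization, TPE hyperparameter search, balanced-accuracy evaluation
and noise/missing-value robustness sweeps.
"""

from .data import (
    DataSplit,
    ExpressionMatrix,
    PairedDataset,
    SampleAnnotation,
    encode_labels,
    match_paired_samples,
    max_norm_normalize,
    read_annotations,
    read_expression_table,
    remove_features,
    split_and_trim,
    write_expression_table,
)
from .synthetic import (
    GeneratorConfig,
    SyntheticDataset,
    generate,
    inject_gaussian_noise,
    inject_missing,
    paper_shaped_preset,
    tiny_preset,
)
from .networks import (
    ArchitectureConfig,
    BatchNormParams,
    ForwardOutputs,
    ModelState,
    batch_norm_forward,
    build_model,
    corruption_layers,
    decode,
    encode,
    load_model,
    predict,
    save_model,
)
from .objectives import (
    LossBreakdown,
    LossWeights,
    MetricReport,
    balanced_accuracy,
    classification_report,
    contractive_penalty,
    cosine_classification_loss,
    kl_gaussian,
    mse,
    subtype_accuracy,
    total_loss,
)
from .training import (
    CrossValidationResult,
    History,
    TrainingConfig,
    cross_validate,
    evaluate,
    extract_cics,
    fit,
)
from .hpo import (
    SearchSpace,
    Trial,
    bayesian_optimize,
    grid_search,
    hpo_objective,
    random_search,
)
from .evaluation import (
    ComparisonResult,
    RobustnessCurve,
    baseline_classifier_compare,
    default_dropout_grid,
    default_noise_grid,
    dimred_compare,
    embed_2d,
    mcnemar_test,
    random_and_majority_baselines,
    robustness_sweep,
)

__version__ = "0.1.0"
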