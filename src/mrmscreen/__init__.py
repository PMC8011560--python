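"""mrmscreen: target-cognizant analysis of MRM chromatograms.

Preprocess multiple-reaction-monitoring traces (smoothing, baseline
correction, standard-anchored retention-time alignment), deconvolve coeluted
peaks with iterative Gaussian fitting, classify peaks into known congener
classes from retention-time features, select the annotated target peak per
class with an L2-norm criterion, screen for consistently co-classified
non-target peaks, and build per-location signal templates.
"""

from .annotate import (
    AnnotatedPeak,
    LocationTemplate,
    NonTargetPeak,
    build_template,
    default_scaling,
    eq_l2_score,
    find_nontarget_peaks,
    select_target_peaks,
)
from .classify import (
    ClassifierModel,
    ConfusionCounts,
    LabeledPeak,
    Metrics,
    PeakFeatureVector,
    compute_metrics,
    extract_features,
    f1_from_precision_recall,
    label_against_manual,
    predict_classes,
    split_train_test,
    train_classifier,
)
from .io_mrm import (
    CALIBRATION_OWNER,
    TIC_CHANNEL,
    CalibrationTable,
    Chromatogram,
    SampleMeta,
    StandardTable,
    accumulate_tic,
    read_chromatogram,
    read_transition_table,
    write_chromatogram,
)
from .peakfit import (
    FitResult,
    FittedPeak,
    detect_peak_regions,
    fit_gaussians,
    goodness_of_fit,
    initial_component_count,
)
from .pipeline import PipelineConfig, run_pipeline
from .preprocess import (
    BaselineConfig,
    SmoothingConfig,
    align_to_standards,
    estimate_baseline,
    savgol_smooth,
    subtract_baseline,
)
from .synthgen import (
    Interferent,
    SimConfig,
    TruePeak,
    default_sim_config,
    separable_feature_benchmark,
    simulate_batch,
    simulate_coeluted_region,
)

__version__ = "0.1.0"
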