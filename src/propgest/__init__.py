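"""propgest: online recognition of wheelchair propulsion gestures from
bilateral wearable IMU streams.

The pipeline: simulate (or load) 17-channel trials at 30 Hz, cut them
into sliding windows, compute 19 time/frequency features per signal,
train one 3-class classifier per body side, fuse the two label streams
into eight specific propulsion gestures, and quantify each detected
propulsion's count, onset and duration.
"""

from importlib import resources as _resources
import json as _json

from .io import (
    GestureAnnotation,
    TrialRecording,
    fsr_boundaries,
    read_annotations,
    read_trial,
    write_annotations,
    write_trial,
)
from .synthetic import (
    ChoreographyPlan,
    GestureSpec,
    SimulatorConfig,
    make_choreography,
    make_corpus,
    synthesize_trial,
)
from .windowing import (
    LabeledDataset,
    Window,
    WindowParams,
    build_dataset,
    count_windows,
    label_window,
    slide,
)
from .features import (
    FilterSpec,
    featurize,
    featurize_windows,
    freq_features,
    select_signals,
    time_features,
)
from .training import (
    GRID,
    SideModel,
    TrainingConfig,
    grid_search,
    load_model,
    save_model,
    select_features,
    sweep_window_params,
    train_side,
)
from .fusion import (
    FUSION_TABLE,
    FusedTimeline,
    PredictionStream,
    PropulsionEvent,
    TimingReport,
    despike,
    extract_events,
    fuse,
    fuse_streams,
    overall_accuracy,
    predict_stream,
    recognize,
    score_timing,
)

__version__ = "0.1.0"


def example_timing() -> dict:
    """The bundled single-choreography timing example (FSR vs detected)."""
    with _resources.files("propgest.data").joinpath("example_timing.json").open() as fh:
        return _json.load(fh)


def example_timing_events() -> tuple[list[PropulsionEvent], list[GestureAnnotation]]:
    """The bundled example as (detected events, reference annotations)."""
    from . import schema

    raw = example_timing()
    events, refs = [], []
    for row in raw["events"]:
        name = schema.ID_TO_GESTURE[row["gesture_id"]]
        events.append(
            PropulsionEvent(
                gesture_id=row["gesture_id"],
                gesture_name=name,
                onset_ms=row["detected_onset_ms"],
                duration_ms=row["detected_duration_ms"],
            )
        )
        refs.append(
            GestureAnnotation(
                label=name,
                onset_ms=row["fsr_onset_ms"],
                duration_ms=row["fsr_duration_ms"],
                source="fsr",
            )
        )
    return events, refs
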