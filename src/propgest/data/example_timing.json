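{
  "description": "Bundled worked example: one choreography's eight propulsion gestures, with reference onsets/durations from the palm force sensor (FSR) and the onsets/durations detected by the fused classifiers. Units: ms.",
  "events": [
    {"gesture_id": 1, "fsr_onset_ms": 4740, "fsr_duration_ms": 1080, "detected_onset_ms": 4680, "detected_duration_ms": 810},
    {"gesture_id": 8, "fsr_onset_ms": 9600, "fsr_duration_ms": 1200, "detected_onset_ms": 9540, "detected_duration_ms": 540},
    {"gesture_id": 2, "fsr_onset_ms": 15030, "fsr_duration_ms": 1260, "detected_onset_ms": 15390, "detected_duration_ms": 450},
    {"gesture_id": 7, "fsr_onset_ms": 21270, "fsr_duration_ms": 1260, "detected_onset_ms": 21330, "detected_duration_ms": 540},
    {"gesture_id": 5, "fsr_onset_ms": 27210, "fsr_duration_ms": 1470, "detected_onset_ms": 27270, "detected_duration_ms": 990},
    {"gesture_id": 4, "fsr_onset_ms": 33390, "fsr_duration_ms": 960, "detected_onset_ms": 33390, "detected_duration_ms": 540},
    {"gesture_id": 6, "fsr_onset_ms": 39120, "fsr_duration_ms": 1320, "detected_onset_ms": 39330, "detected_duration_ms": 630},
    {"gesture_id": 3, "fsr_onset_ms": 46350, "fsr_duration_ms": 1140, "detected_onset_ms": 46530, "detected_duration_ms": 540}
  ],
  "side_classifier_accuracy": {"right": 0.9614, "left": 0.9391}
}
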