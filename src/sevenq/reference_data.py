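"""Published single-EV concentration summaries for the Exomap1 mouse model.

Detected-exosome concentrations (EV/ROI/uL) reported for plasma and CSF of
Exomap1 reporter mice, by capture antibody and stain panel. The hepatocyte
experiment activated the HsCD81mNG tracer in liver via AAV8/TBG-Cre; the
neuron experiment used a Camk2a-Cre driver; matched reporter-only animals
serve as tracer-free controls. These summaries are inputs to the
contribution arithmetic (tracer-specific / total concentration), which this
package recomputes; the absolute values themselves depend on the original
microscope data and are not simulation targets.

Each entry carries the published mean, median, SEM and CV over ROIs.
``IN_TEXT`` holds the values quoted in the running text of the source study
where they were rounded differently from the tabulated means (35 vs 35.4 and
5 vs 4.9 EV/ROI/uL); the headline ~17% and 7-fold figures derive from the
in-text values.
"""

# plasma, hepatocyte tracer (AAV8/TBG-Cre) vs reporter-only control;
# 20 ROIs, 1 uL (MmCD81 capture) or 5 uL (HsCD81 capture) plasma
HEPATOCYTE_PLASMA = {
    "cre_mm_capture_mm_stain": {"mean": 202.0, "median": 198.0, "sem": 5.8, "cv": 0.13},
    "ctrl_mm_capture_mm_stain": {"mean": 517.0, "median": 535.0, "sem": 19.9, "cv": 0.17},
    "cre_mm_capture_hs_stain": {"mean": 23.0, "median": 22.0, "sem": 1.4, "cv": 0.28},
    "ctrl_mm_capture_hs_stain": {"mean": 0.7, "median": 0.0, "sem": 0.2, "cv": 1.16},
    "cre_hs_capture_mm_stain": {"mean": 35.4, "median": 32.4, "sem": 2.6, "cv": 0.33},
    "ctrl_hs_capture_mm_stain": {"mean": 0.8, "median": 0.7, "sem": 0.1, "cv": 0.70},
    "cre_hs_capture_hs_stain": {"mean": 4.9, "median": 5.1, "sem": 0.4, "cv": 0.33},
    "ctrl_hs_capture_hs_stain": {"mean": 0.5, "median": 0.3, "sem": 0.1, "cv": 1.13},
}

# plasma, neuron tracer (Camk2a-Cre) vs reporter-only control; 20 ROIs
NEURON_PLASMA = {
    "cre_mm_capture": {"mean": 259.0, "median": 254.0, "sem": 7.1, "cv": 0.12},
    "cre_hs_capture": {"mean": 3.3, "median": 3.2, "sem": 0.2, "cv": 0.28},
    "ctrl_mm_capture": {"mean": 648.0, "median": 654.0, "sem": 29.0, "cv": 0.20},
    "ctrl_hs_capture": {"mean": 1.7, "median": 1.3, "sem": 0.2, "cv": 0.60},
}

# CSF, neuron tracer (Camk2a-Cre) vs reporter-only control; 10 ROIs,
# 1 uL (MmCD81 capture) or 6 uL (HsCD81 capture) CSF
NEURON_CSF = {
    "cre_mm_capture": {"mean": 42.0, "median": 43.0, "sem": 3.1, "cv": 0.24},
    "cre_hs_capture": {"mean": 0.4, "median": 0.3, "sem": 0.1, "cv": 0.71},
    "ctrl_mm_capture": {"mean": 161.0, "median": 156.0, "sem": 15.0, "cv": 0.29},
    "ctrl_hs_capture": {"mean": 0.7, "median": 0.7, "sem": 0.1, "cv": 0.36},
}

# in-text rounded concentrations quoted with the headline ratios
IN_TEXT = {
    "hepatocyte_hs_capture_mm_stain": 35.0,
    "hepatocyte_hs_capture_hs_stain": 5.0,
}
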