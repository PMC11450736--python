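# Simulated plasma experiment with a hepatocyte-activated HsCD81 tracer
# (labeled fraction 0.15) and a tracer-free control animal. Capture on the
# mouse CD81 antibody measures the total exosome pool; capture on the human
# CD81 antibody measures the tracer-positive pool. Concentrations are scaled
# down from the published plasma counts (~200-500 EV/ROI/uL) to keep the
# demonstration fast; the contribution fraction is volume- and
# concentration-invariant.
population:
  n_ev_per_roi_mean: 15.0
  labeled_fraction: 0.15
  tspan_mean: {MmCD9: 8.0, MmCD63: 8.0, MmCD81: 8.0, HsCD81: 8.0}

segmentation:
  min_cluster_size: 40
  density_factor_alpha: 2.0

phenotype:
  loc_per_ab: 14.0
  min_proteins: 3

conditions:
  cre_mm_capture:
    capture_species: MmCD81
    stain_panel: [MmCD9, MmCD63, MmCD81]
    volume_ul: 1.0
    n_roi: 20
  cre_hs_capture:
    capture_species: HsCD81
    stain_panel: [MmCD9, MmCD63, MmCD81]
    volume_ul: 5.0
    n_roi: 20

contrasts:
  hepatocyte_contribution:
    specific: cre_hs_capture
    total: cre_mm_capture
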