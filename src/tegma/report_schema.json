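{
  "exclusions": {
    "n_initial": null,
    "n_missing_excluded": null,
    "n_outlier_excluded": null,
    "n_final": null,
    "max_crt_r": null
  },
  "summaries": {
    "*": {
      "n": null,
      "median": null,
      "q1": null,
      "q3": null,
      "min": null,
      "max": null
    }
  },
  "channels": {
    "*": {
      "kind": null,
      "params": null,
      "r": null,
      "abs_r": null,
      "p_value": null,
      "r2": null,
      "mae": null,
      "rmse": null,
      "n": null
    }
  },
  "cutoffs": {
    "*": {
      "estimate": {
        "y_target": null,
        "point": null,
        "boot_median": null,
        "boot_q25": null,
        "boot_q75": null,
        "boot_ci_lo": null,
        "boot_ci_hi": null,
        "n_boot_requested": null,
        "n_boot_succeeded": null
      },
      "metrics": {
        "tp": null,
        "fp": null,
        "tn": null,
        "fn": null,
        "sensitivity": null,
        "specificity": null,
        "ppv": null,
        "npv": null,
        "accuracy": null
      }
    }
  },
  "provenance": {
    "config": null,
    "seed": null,
    "package": null,
    "version": null
  }
}
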