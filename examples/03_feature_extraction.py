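"""Extract radiomic features from one phantom patient.

The extractor covers first-order intensity statistics, 3-D shape, and three
texture families (co-occurrence, run-length, size-zone) over a filter bank
(original image, Laplacian-of-Gaussian scales, stationary coiflet-1 wavelet
sub-bands) and fixed-bin-count discretizations.
"""

from robustrad import (PreprocessConfig, expected_feature_count, extract_all,
                       generate_phantom_cohort)

patient = generate_phantom_cohort(1, image_shape=(40, 40, 40),
                                  seed=5).patients[0]

# compact configuration: one LoG scale, two bin counts, no wavelet bank
config = PreprocessConfig(bin_counts=(25, 50), log_sigmas_mm=(3.0,),
                          wavelet=False)
features = extract_all(patient.image, patient.mask, config)

print(f"extracted {len(features)} features "
      f"(expected {expected_feature_count(config)})")
for name in ("original_na_shape_volume", "original_na_shape_sphericity",
             "original_raw_firstorder_mean", "original_bin50_glcm_contrast",
             "original_bin50_glrlm_run_entropy",
             "log-sigma-3mm_bin50_glszm_zone_entropy"):
    print(f"  {name} = {features[name]:.4g}")
# Names follow {image}_{bins}_{class}_{feature}; the full default
# configuration (3 LoG scales, 8 wavelet sub-bands, 7 bin counts) yields
# several thousand features per patient.
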