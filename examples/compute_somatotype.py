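"""Compute one subject's somatotype through both measurement pathways.

Builds a manually measured record and a 3D-scan record for the same
physique and prints the three components each pathway yields, plus the
derived indices.  The components are endomorphy (relative fatness),
mesomorphy (musculoskeletal robustness) and ectomorphy (linearity), each
on the open-ended Heath-Carter scale floored at 0.1.
"""

import somascan as sm

manual = sm.ManualAnthropometry(
    subject_id="demo",
    sex=sm.Sex.male,
    age=24,
    height=170.0,
    weight=69.86,
    skinfold_triceps=12,
    skinfold_subscapular=14,
    skinfold_supraspinale=10,
    skinfold_medial_calf=10,
    girth_biceps=30,
    girth_calf=37,
    breadth_humerus=7,
    breadth_femur=10,
)

scan = sm.ScanAnthropometry(
    subject_id="demo",
    sex=sm.Sex.male,
    age=24,
    weight=69.86,  # entered manually; the scanner cannot weigh
    c7_height=1450,  # floor-to-C7 landmark, mm
    circ_waist=85,
    circ_hips=98,
    circ_neck=38,
    girth_biceps=30,
    girth_calf=37,
    breadth_humerus=7,
    breadth_femur=10,
)

for result in (sm.somatotype_manual(manual), sm.somatotype_scan(scan)):
    endo, meso, ecto = result.components
    print(f"{result.pathway.value:>6} pathway: "
          f"endo {endo:.2f}  meso {meso:.2f}  ecto {ecto:.2f}  "
          f"HWR {result.hwr:.2f}  BMI {result.bmi:.2f}  "
          f"category: {result.category}")
    if result.bf_percent is not None:
        print(f"        circumference body fat: {result.bf_percent:.2f}% "
              f"(endomorphy = BF%/5)")

# The two pathways measure the same physique with different instruments:
# close components mean the scan substitutions (C7-predicted height, Navy
# body fat, uncorrected girths) reproduce the caliper-based reference.
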