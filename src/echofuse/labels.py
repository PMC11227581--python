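"""The 14-category standard-plane label set (13 anatomical planes + background)."""

PLANE_CLASSES = (
    "3VT",        # three-vessel tracheal view of the heart
    "4CH",        # four-chamber view of the heart
    "LVOT",       # left ventricular outflow tract
    "RVOT",       # right ventricular outflow tract
    "BrainTv.",   # transventricular plane of the brain
    "BrainCb.",   # transcerebellar plane of the brain
    "abdomen",
    "femur",
    "kidneys",
    "lips",
    "profile",
    "SpineCor.",  # spine, coronal plane
    "SpineSag.",  # spine, sagittal plane
    "background",
)

N_PLANE_CLASSES = len(PLANE_CLASSES)
BACKGROUND_CLASS = N_PLANE_CLASSES - 1
N_ANATOMY_CLASSES = N_PLANE_CLASSES - 1
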