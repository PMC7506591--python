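"""Category vocabulary shared by every stage of the contouring pipeline.

Six anatomical categories are contoured (lungs, airway, heart, spinal cord,
body and the gross tumor volume) plus one synthetic ``background`` category
covering the air outside the patient, which is needed so that the label maps
tile the region of interest completely.
"""

from __future__ import annotations

# Integer ids used in label maps.  Background is 0 so that an all-zero array
# is a valid "nothing segmented" label map.
CATEGORY_IDS: dict[str, int] = {
    "background": 0,
    "lungs": 1,
    "airway": 2,
    "heart": 3,
    "spinal_cord": 4,
    "body": 5,
    "gtv": 6,
}

ID_TO_CATEGORY: dict[int, str] = {v: k for k, v in CATEGORY_IDS.items()}

#: The six user-facing categories, in their conventional reporting order.
ORGAN_CATEGORIES: tuple[str, ...] = (
    "lungs",
    "airway",
    "heart",
    "spinal_cord",
    "body",
    "gtv",
)

#: Fixed priority used to break exact probability ties in the per-pixel
#: argmax.  Earlier entries win.
TIE_PRIORITY: tuple[str, ...] = (
    "body",
    "lungs",
    "airway",
    "heart",
    "spinal_cord",
    "gtv",
    "background",
)


def category_id(name: str) -> int:
    try:
        return CATEGORY_IDS[name]
    except KeyError:
        raise ValueError(f"unknown category {name!r}") from None
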