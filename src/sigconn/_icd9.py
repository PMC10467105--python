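"""Static ICD-9-CM top-level chapter ranges."""

from __future__ import annotations

UNCLASSIFIED = "UNCLASSIFIED"

# (low category, high category, chapter label); categories are the 3-digit
# code prefixes before any decimal part.
CHAPTERS: list[tuple[int, int, str]] = [
    (1, 139, "INFECTIOUS AND PARASITIC DISEASES"),
    (140, 239, "NEOPLASMS"),
    (240, 279, "ENDOCRINE, NUTRITIONAL AND METABOLIC DISEASES, AND IMMUNITY DISORDERS"),
    (280, 289, "DISEASES OF THE BLOOD AND BLOOD-FORMING ORGANS"),
    (290, 319, "MENTAL DISORDERS"),
    (320, 389, "DISEASES OF THE NERVOUS SYSTEM AND SENSE ORGANS"),
    (390, 459, "DISEASES OF THE CIRCULATORY SYSTEM"),
    (460, 519, "DISEASES OF THE RESPIRATORY SYSTEM"),
    (520, 579, "DISEASES OF THE DIGESTIVE SYSTEM"),
    (580, 629, "DISEASES OF THE GENITOURINARY SYSTEM"),
    (630, 679, "COMPLICATIONS OF PREGNANCY, CHILDBIRTH, AND THE PUERPERIUM"),
    (680, 709, "DISEASES OF THE SKIN AND SUBCUTANEOUS TISSUE"),
    (710, 739, "DISEASES OF THE MUSCULOSKELETAL SYSTEM AND CONNECTIVE TISSUE"),
    (740, 759, "CONGENITAL ANOMALIES"),
    (760, 779, "CERTAIN CONDITIONS ORIGINATING IN THE PERINATAL PERIOD"),
    (780, 799, "SYMPTOMS, SIGNS, AND ILL-DEFINED CONDITIONS"),
    (800, 999, "INJURY AND POISONING"),
]

PREFIX_CHAPTERS: dict[str, str] = {
    "V": "SUPPLEMENTARY CLASSIFICATION OF FACTORS INFLUENCING HEALTH STATUS",
    "E": "SUPPLEMENTARY CLASSIFICATION OF EXTERNAL CAUSES OF INJURY AND POISONING",
}


def chapter_of(code: str) -> str:
    """Top-level chapter for one ICD-9 code, or UNCLASSIFIED."""
    code = str(code).strip().upper()
    if not code:
        return UNCLASSIFIED
    if code[0] in PREFIX_CHAPTERS:
        return PREFIX_CHAPTERS[code[0]]
    category = code.split(".")[0]
    try:
        num = int(category)
    except ValueError:
        return UNCLASSIFIED
    for lo, hi, label in CHAPTERS:
        if lo <= num <= hi:
            return label
    return UNCLASSIFIED
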