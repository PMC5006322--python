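"""Default tissue panel and tissue-to-organ mapping.

The atlas samples 23 tissues of toxicologic interest from 14 organs in
Sprague Dawley rats (5 males + 5 females).  Multi-tissue organs: kidney
(whole, medulla, cortex), skeletal muscle (soleus, biceps femoris),
stomach (glandular, non-glandular), intestine (duodenum, jejunum, ileum)
and brain (cerebrum, cerebellum, hippocampus, brainstem); the remaining
nine organs contribute one tissue each.  Testis is male-only; ovary and
uterus are female-only, so a full animal panel yields 215 samples
(10 x 20 mixed-sex tissues + 5 x 3 single-sex tissues).

The mapping is a package default, overridable everywhere it is consumed
(YAML config or an explicit dict argument).
"""

from __future__ import annotations

DEFAULT_ORGAN_MAP: dict[str, str] = {
    "liver": "liver",
    "kidney": "kidney",
    "kidney_medulla": "kidney",
    "kidney_cortex": "kidney",
    "heart": "heart",
    "pancreas": "pancreas",
    "adrenal": "adrenal",
    "stomach_glandular": "stomach",
    "stomach_nonglandular": "stomach",
    "duodenum": "intestine",
    "jejunum": "intestine",
    "ileum": "intestine",
    "cerebrum": "brain",
    "cerebellum": "brain",
    "hippocampus": "brain",
    "brainstem": "brain",
    "dorsal_root_ganglion": "dorsal_root_ganglion",
    "soleus": "muscle",
    "biceps_femoris": "muscle",
    "testis": "testis",
    "ovary": "ovary",
    "uterus": "uterus",
    "whole_blood": "whole_blood",
}

DEFAULT_TISSUES: list[str] = list(DEFAULT_ORGAN_MAP)

#: Tissues only present in one sex; value is the sex ("M" or "F") that has them.
SEX_RESTRICTED: dict[str, str] = {"testis": "M", "ovary": "F", "uterus": "F"}


def organs_of(organ_map: dict[str, str] | None = None) -> dict[str, list[str]]:
    """Invert a tissue->organ map into organ -> [tissues] (insertion order)."""
    omap = DEFAULT_ORGAN_MAP if organ_map is None else organ_map
    out: dict[str, list[str]] = {}
    for tissue, organ in omap.items():
        out.setdefault(organ, []).append(tissue)
    return out


def validate_organ_map(organ_map: dict[str, str], tissues: list[str]) -> None:
    """Every tissue must map to exactly one organ; raise on unmapped tissues."""
    missing = [t for t in tissues if t not in organ_map]
    if missing:
        raise ValueError(f"tissues missing from organ map: {missing}")
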