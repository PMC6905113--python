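"""Published gold-standard cause compositions for the PHMRC and IMMCMC studies.

Number of gold-standard (level 1/2) deaths by cause and age module in the
two source datasets: the public PHMRC gold-standard VA release and the
IMMCMC study (Bohol, Philippines; Chandpur/Comilla, Bangladesh; Central
and Eastern Highlands, Papua New Guinea). These counts parameterize the
PHMRC-like synthetic-data generator and the combined-column arithmetic
used by the acceptance checks.

Each table maps cause → (PHMRC count, IMMCMC count), listed in decreasing
order of the combined count.
"""

from __future__ import annotations

ADULT: dict[str, tuple[int, int]] = {
    "Stroke": (630, 691),
    "Other Non-communicable Diseases": (598, 275),
    "Pneumonia": (539, 243),
    "Acute Myocardial Infarction": (400, 192),
    "Maternal": (467, 72),
    "AIDS": (501, 8),
    "Other Cardiovascular Diseases": (416, 79),
    "Diabetes": (414, 70),
    "Renal Failure": (413, 62),
    "Road Traffic": (202, 186),
    "Other Infectious Diseases": (263, 97),
    "Cirrhosis": (313, 29),
    "TB": (275, 55),
    "Diarrhea/Dysentery": (228, 27),
    "Falls": (173, 57),
    "COPD": (171, 45),
    "Homicide": (167, 46),
    "Breast Cancer": (194, 9),
    "Suicide": (124, 53),
    "Leukemia/Lymphomas": (155, 18),
    "Cervical Cancer": (155, 3),
    "Poisonings": (86, 57),
    "Other Injuries": (103, 37),
    "Fires": (122, 11),
    "Colorectal Cancer": (99, 23),
    "Lung Cancer": (106, 13),
    "Drowning": (106, 1),
    "Malaria": (100, 0),
    "Stomach Cancer": (62, 11),
    "Bite of Venomous Animal": (66, 3),
    "Asthma": (47, 11),
    "Prostate Cancer": (48, 2),
    "Epilepsy": (48, 1),
    "Esophageal Cancer": (40, 4),
}

CHILD: dict[str, tuple[int, int]] = {
    "Pneumonia": (531, 124),
    "Diarrhea/Dysentery": (256, 38),
    "Other Defined Causes of Child Deaths": (194, 43),
    "Sepsis": (138, 11),
    "Malaria": (116, 0),
    "Road Traffic": (92, 10),
    "Other Cardiovascular Diseases": (76, 9),
    "Drowning": (83, 1),
    "Other Infectious Diseases": (67, 10),
    "Fires": (68, 3),
    "Meningitis": (58, 12),
    "Hemorrhagic fever": (51, 17),
    "Other Digestive Diseases": (48, 16),
    "Falls": (49, 10),
    "Bite of Venomous Animal": (54, 1),
    "Violent Death": (52, 0),
    "Encephalitis": (41, 1),
    "Other Cancers": (28, 8),
    "Poisonings": (18, 6),
    "Measles": (23, 0),
    "AIDS": (20, 0),
}

NEONATE: dict[str, tuple[int, int]] = {
    "Stillbirth": (1002, 370),
    "Preterm Delivery": (659, 172),
    "Birth asphyxia": (461, 88),
    "Congenital malformation": (248, 33),
    "Meningitis/Sepsis": (165, 32),
    "Pneumonia": (82, 6),
}

TABLES: dict[str, dict[str, tuple[int, int]]] = {
    "adult": ADULT,
    "child": CHILD,
    "neonate": NEONATE,
}


def counts(module: str, dataset: str = "combined") -> dict[str, int]:
    """Cause counts for one module; ``dataset`` ∈ {phmrc, immcmc, combined}."""
    table = TABLES[module]
    idx = {"phmrc": 0, "immcmc": 1}.get(dataset)
    if idx is None:
        if dataset != "combined":
            raise ValueError(f"unknown dataset {dataset!r}")
        return {c: p + i for c, (p, i) in table.items()}
    return {c: pair[idx] for c, pair in table.items()}


def fractions(module: str, dataset: str = "combined") -> dict[str, float]:
    """Within-module cause fractions recomputed from the listed counts."""
    n = counts(module, dataset)
    total = sum(n.values())
    return {c: v / total for c, v in n.items()}
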