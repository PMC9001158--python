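"""Published method-comparison counts for the Luxembourg water-frog survey.

These confusion-table counts compare MND1 single-marker species calls
against ddRAD-based identification for 382 toe-clip samples, and for 20
frogs re-sampled with buccal and skin swabs.  They serve as reference
inputs for the concordance statistics: rows are MND1 calls, columns ddRAD
calls, ``UNIDENTIFIED`` covering both failed identifications and missing
data.
"""

from .markers import ESCULENTUS, LESSONAE, RR_GENOTYPE, UNIDENTIFIED

#: MND1 (toe-clip DNA) vs ddRAD, all 382 individuals.
TOE_CLIP_MND1_VS_DDRAD = {
    (LESSONAE, LESSONAE): 130,
    (LESSONAE, ESCULENTUS): 8,
    (LESSONAE, RR_GENOTYPE): 0,
    (LESSONAE, UNIDENTIFIED): 0,
    (ESCULENTUS, LESSONAE): 3,
    (ESCULENTUS, ESCULENTUS): 215,
    (ESCULENTUS, RR_GENOTYPE): 3,
    (ESCULENTUS, UNIDENTIFIED): 3,
    (RR_GENOTYPE, LESSONAE): 0,
    (RR_GENOTYPE, ESCULENTUS): 0,
    (RR_GENOTYPE, RR_GENOTYPE): 4,
    (RR_GENOTYPE, UNIDENTIFIED): 0,
    (UNIDENTIFIED, LESSONAE): 7,
    (UNIDENTIFIED, ESCULENTUS): 9,
    (UNIDENTIFIED, RR_GENOTYPE): 0,
    (UNIDENTIFIED, UNIDENTIFIED): 0,
}

#: MND1 from buccal-swab DNA vs ddRAD, 20 individuals.
BUCCAL_MND1_VS_DDRAD = {
    (LESSONAE, LESSONAE): 6,
    (LESSONAE, ESCULENTUS): 0,
    (LESSONAE, RR_GENOTYPE): 0,
    (ESCULENTUS, LESSONAE): 0,
    (ESCULENTUS, ESCULENTUS): 13,
    (ESCULENTUS, RR_GENOTYPE): 0,
    (RR_GENOTYPE, LESSONAE): 0,
    (RR_GENOTYPE, ESCULENTUS): 0,
    (RR_GENOTYPE, RR_GENOTYPE): 1,
}

#: MND1 from skin-swab DNA vs ddRAD, 20 individuals.  Skin swabs yield
#: little template DNA; allelic dropout then makes hybrids look homozygous,
#: which is why 12 MND1 lessonae calls here contradict the ddRAD genotype.
SKIN_MND1_VS_DDRAD = {
    (LESSONAE, LESSONAE): 6,
    (LESSONAE, ESCULENTUS): 11,
    (LESSONAE, RR_GENOTYPE): 1,
    (ESCULENTUS, LESSONAE): 0,
    (ESCULENTUS, ESCULENTUS): 2,
    (ESCULENTUS, RR_GENOTYPE): 0,
    (RR_GENOTYPE, LESSONAE): 0,
    (RR_GENOTYPE, ESCULENTUS): 0,
    (RR_GENOTYPE, RR_GENOTYPE): 0,
}
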