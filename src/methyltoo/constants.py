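"""Shared label vocabulary and serialization sentinels."""

#: The five tumor classes the atlas distinguishes, in canonical order.
TUMOR_CLASSES: tuple[str, ...] = ("Breast", "CRC", "Gastric", "Liver", "Lung")

#: All atlas classes: five tumor types plus white blood cells (WBC),
#: the dominant cfDNA contributor.
ALL_CLASSES: tuple[str, ...] = TUMOR_CLASSES + ("WBC",)

#: Sentinel for samples whose class is not known (e.g. test nodes).
UNKNOWN_LABEL = "unknown"

#: On-disk encoding of a missing value in TSV matrices.
NA_TOKEN = "NA"
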