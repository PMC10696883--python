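"""Bundled reference tables.

The GRHL1 isothermal-titration-calorimetry ligand panel: a positive-control
duplex carrying the canonical GRHL1 motif, a non-canonical ("Novel")
binding sequence lacking the CNNG core, their position-12 single-base
variants, and a MYOD-derived negative control. Kd in µM; NBD = no binding
detected (censored at the assay's 9 µM detection threshold). Thermodynamic
columns (ΔH, -TΔS, ΔG, kcal/mol) are carried for reporting only.
"""

from __future__ import annotations

from crnn_tfbs.evaluate import AffinityRecord, parse_affinity_table

GRHL1_ITC_TSV = """\
ligand_id\tsequence\tkd_uM\tdH\tminus_TdS\tdG
Pos_Ctrl\tGGGCAAAACCGGTTTTGCGG\t0.11\t-93.7\t55.8\t-37.9
Pos_Ctrl_V1\tGGGCAAAACCGATTTTGCGG\t3.40\t-117.0\t87.7\t-29.7
Pos_Ctrl_V2\tGGGCAAAACCGCTTTTGCGG\t1.54\t-81.7\t50.0\t-31.5
Pos_Ctrl_V3\tGGGCAAAACCGTTTTTGCGG\t4.35\t-55.5\t26.4\t-29.1
Novel\tAGGTTTTTCCACTTTGGGGC\t0.18\t-52.6\t16.0\t-36.6
Novel_V1\tAGGTTTTTCCAATTTGGGGC\tNBD\t-\t-\t-
Novel_V2\tAGGTTTTTCCAGTTTGGGGC\t0.21\t-103.1\t62.4\t-41.0
Novel_V3\tAGGTTTTTCCATTTTGGGGC\tNBD\t-\t-\t-
Neg_Ctrl\tGCAAAAAGGAGTCATTGGTG\tNBD\t-\t-\t-
"""

#: the base position (1-based) at which the bundled variant panel mutates
VARIANT_POSITION = 12


def grhl1_itc_panel() -> list[AffinityRecord]:
    """The bundled ligand panel as :class:`AffinityRecord` objects."""
    return parse_affinity_table(GRHL1_ITC_TSV)
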