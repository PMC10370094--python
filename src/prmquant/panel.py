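"""Reference PRM panel for the TTR-mistargeting proximity-labeling assay.

The 20 targeted peptides of the assay with the coefficients of variation
measured over 8 technical replicate injections of one eluate digest, both
from raw peak areas and from areas normalized by the MS1 total-ion-current
chromatogram.  ``precursor_quantified`` marks peptides quantified from the
precursor ion chromatogram (little MS1 interference) rather than from
summed fragment areas.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PanelEntry:
    protein: str
    peptide: str
    charge: int
    cv_raw: float
    cv_tic: float
    precursor_quantified: bool = False


PANEL: tuple[PanelEntry, ...] = (
    PanelEntry("FLAG-TTR", "AADDTWEPFASGK", 2, 0.0976, 0.0485),
    PanelEntry("cytAPEX", "LAFHSAGTFDK", 3, 0.1392, 0.0773, True),
    PanelEntry("cytAPEX", "EGLLQLPSDK", 2, 0.0787, 0.0551, True),
    PanelEntry("cytAPEX", "ALLSDPVFRPLVDK", 2, 0.0685, 0.0914, True),
    PanelEntry("cytAPEX", "LSELGFADALQLPPLER", 2, 0.1799, 0.1126, True),
    PanelEntry("GAPDH", "GALQNIIPASTGAAK", 2, 0.0793, 0.0614),
    PanelEntry("beta/gamma-Actin", "VAPEEHPVLLTEAPLNPK", 3, 0.0995, 0.0511, True),
    PanelEntry("alpha-Tubulin 1 or 3", "TIGGGDDSFNTFFSETGAGK", 2, 0.0424, 0.0564, True),
    PanelEntry("alpha-Tubulin 1", "AVFVDLEPTVIDEVR", 2, 0.1114, 0.0747, True),
    PanelEntry("alpha-Tubulin 1 or 3", "DVNAAIATIK", 2, 0.1031, 0.0518, True),
    PanelEntry("HSPA1A", "AQIHDLVLVGGSTR", 2, 0.1151, 0.1357),
    PanelEntry("BiP", "TWNDPSVQQDIK", 2, 0.1126, 0.0461),
    PanelEntry("BiP", "IEWLESHQDADIEDFK", 3, 0.0736, 0.0591),
    PanelEntry("Avidin", "SSVNDIGDDWK", 2, 0.1098, 0.0395, True),
    PanelEntry("PC", "ENNVDAVHPGYGFLSER", 3, 0.0802, 0.0760),
    PanelEntry("PC", "VVEIAPAAHLDPQLR", 3, 0.0560, 0.0586),
    PanelEntry("PC", "LDNASAFQGAVISPHYDSLLVK", 3, 0.0622, 0.0681),
    PanelEntry("PC", "VFDYSEYWEGAR", 2, 0.0801, 0.0426),
    PanelEntry("PC", "AEAEAQAEELSFPR", 2, 0.0845, 0.0549),
    PanelEntry("PC", "DFTATFGPLDSLNTR", 2, 0.1039, 0.0373),
)

#: Mature chain of human transthyretin (UniProt P02766, residues 21-147).
#: The assay's analyte construct is an N-terminally FLAG-tagged form of this
#: protein; the panel's TTR peptide is fully tryptic within this sequence.
TTR_MATURE = (
    "GPTGTGESKCPLMVKVLDAVRGSPAINVAVHVFRKAADDTWEPFASGKTSESGELHGLTTEEEFVEGIYK"
    "VEIDTKSYWKALGISPFHEHAEVVFTANDSGPRRYTIAALLSPYSYSTTAVVTNPKE"
)
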