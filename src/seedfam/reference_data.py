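"""Published LC-MS validation set for Zinnia haageana PawS-derived peptides.

Eleven PDPs predicted from Z. haageana seed transcriptomes whose masses were
confirmed in the LC-MS profile of seed extracts.  Each record carries the
peptide sequence, whether the mature form is backbone-cyclic (all but the
first, which retains a free C-terminus ending in Tyr), and the published
predicted and observed m/z of the doubly charged [M+2H]2+ ion with the Cys
pair oxidised to a disulfide.  Masses in Da, printed to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ValidatedPdp:
    sequence: str
    cyclic: bool
    predicted_mz: float  # published prediction, [M+2H]2+
    observed_mz: float  # published LC-MS observation
    lc_confirmed: bool  # retention time confirmed against a synthetic standard


ZINNIA_PDPS: tuple[ValidatedPdp, ...] = (
    ValidatedPdp("GICFKDPFGSTLCAPY", False, 858.88, 858.86, True),
    ValidatedPdp("GICFKDPFGSTLCAPD", True, 825.86, 825.88, True),
    ValidatedPdp("GQCEILPWFPFPEACGPD", True, 993.43, 993.43, True),
    ValidatedPdp("GPCYSYQSCFPD", True, 673.75, 673.75, True),
    ValidatedPdp("GRPCYTLQSCFPD", True, 733.81, 733.83, True),
    ValidatedPdp("GLCTILPWPPYLEVCGLD", True, 984.98, 984.98, True),
    ValidatedPdp("GPCFPMGPWGPFCIPD", True, 850.86, 850.86, True),
    ValidatedPdp("GRGCFGFPPICFPD", True, 746.83, 746.83, False),
    ValidatedPdp("SAACSHLPPGLREMCAAWSFD", True, 1114.99, 1114.97, False),
    ValidatedPdp("SAACSHLQPVLREMCVARFD", True, 1107.02, 1107.01, False),
    ValidatedPdp("GAACSHIEPGLREMCAAWSFFD", True, 1189.51, 1189.48, False),
)
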