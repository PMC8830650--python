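# SYNTHETIC surrogate parameters for the 3-state membrane-topology model
# (states Inside / Membrane / Outside over the protein alphabet).
#
# These numbers are NOT transcribed from any published parameter set; they
# were constructed once from first principles and are labeled synthetic:
#   - transitions between I and O are exactly 0 in both directions (a chain
#     cannot jump across the membrane without traversing it), and the I and
#     M self-transitions are close to 1;
#   - the M emission row is a Kyte-Doolittle hydropathy-weighted amino-acid
#     composition (background * exp(KD/2), normalized), giving the membrane
#     state its hydrophobic bias;
#   - the I row is Swiss-Prot background composition with K and R boosted
#     1.6x (positive-inside rule); the O row boosts polar residues.
name: tm_p18599_synthetic
notes: >
  Synthetic surrogate parameters for the transmembrane worked example;
  emissions derive from Kyte-Doolittle hydropathy over Swiss-Prot
  background frequencies, transitions satisfy the structural constraint
  a(I->O) = a(O->I) = 0 with near-1 self-transitions for I and M.
alphabet:
  kind: protein
states: [I, M, O]
prior: [0.5, 0.1, 0.4]
transitions:
  I: [0.98, 0.02, 0.0]
  M: [0.05, 0.9, 0.05]
  O: [0.0, 0.03, 0.97]
emissions:
  I: [0.07739154876791907, 0.012836128548674228, 0.05115712545676006, 0.06315000468471847,
    0.036166026421812054, 0.06633561322964492, 0.02126862175583248, 0.055560760798276036,
    0.08724819638339738, 0.09041506605453015, 0.02258034292139043, 0.038039913801180554,
    0.04422374215309661, 0.03682188700459103, 0.08290077766326247, 0.061838283519160514,
    0.05012648739810738, 0.06427433711233956, 0.010306380586526751, 0.027358755738780105]
  M: [0.08208651222129708, 0.019320367889650327, 0.003833575506932919, 0.0047322891788878895,
    0.06324501524506011, 0.023420765382941834, 0.001851745971063876, 0.22732332509104383,
    0.003345611183427825, 0.2606835047507112, 0.025178132961061275, 0.002850607428232171,
    0.008569059045591097, 0.0027593318209242442, 0.002354991095140758, 0.017875280481019128,
    0.015232719173455764, 0.22634413727734054, 0.0028339154607914443, 0.006159112835426815]
  O: [0.07657294360856952, 0.012700355053721578, 0.06073921628611953, 0.07497844647773731,
    0.03578348212216444, 0.07219734683093697, 0.021043653994122613, 0.05497306968508682,
    0.0539533331479267, 0.0894587053054111, 0.022341500495962775, 0.048928813119374075,
    0.043755967776325434, 0.03643240537308452, 0.05126493682268636, 0.07953944989848988,
    0.06447516014498801, 0.06359447859016788, 0.010197365371601265, 0.02706936989552336]
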