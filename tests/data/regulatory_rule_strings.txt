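# Regulatory-rule strings from published E. coli / S. typhimurium
# integrated-model refinements (original and refined forms), used as
# parser round-trip fixtures. One rule per line.
(NOT MetJ)
(NagC)
(ON)
(NOT val-L(e)>0 )
(ilvY)
(ilvY AND NOT (val-L(e)>0)) OR (NOT ilvY)
(Crp AND (NOT Lrp OR (leu-L(e)>0)))
((Crp AND (NOT Lrp OR (leu-L(e)>0)))) OR (ser-L(e)>0)
(NOT Lrp OR (leu-L(e)>0))
(NOT GcvB)
(NOT GcvR AND GcvA)
(NOT (rib-D(e)>0))
(NOT ((all-D(e)>0) OR (rib-D(e)>0)))
(SoxS)
(NOT ArgR)
((NOT(Growth>0) AND RpoS) OR (NRI_hi AND RpoN)) AND (NOT Lrp OR (leu-L(e)>0))
((NOT(Growth>0) AND RpoS) OR (NRI_hi AND RpoN))
(NOT (PurR))
(NOT (PurR)) AND (NOT (AGMT>0))
(MetR)
(metR) OR (met-L(e)>0)
(NOT (thr-L(e)>0 OR ile-L(e)>0)) AND (NOT Lrp OR (leu-L(e)>0))
(NOT (thr-L(e)>0 OR ile-L(e)>0))
(RhaR)
(RhaR OR (RhaR AND Crp))
(rmn(e)>0)
(rmn(e)>0 OR lyx(e)>0 OR man(e))
(Lrp AND NOT (leu-L(e)>0) OR (NOT (Crp)))
(Lrp AND NOT (leu-L(e)>0))
(NOT(leu-L(e)>0) AND Lrp)
NOT(leu-L(e)>0)
(NOT(leu-L(e)>0 OR val-L(e)>0) AND Crp)
(("CRP noMAN") AND NOT(ArcA) AND (DcuR))
(ppa(e)>0)
(PrpR AND RpoN AND (HimA AND HimD))
(MCITS>0)
((NOT (Crp OR FadR OR OmpR)))
(((((FucR) OR (rmn(e)>0)) AND (NOT (o2(e)>0))) AND Crp) OR (((FucR) OR (rmn(e)>0)) AND (NOT (o2(e)>0))))
(fuc-L(e)>0 OR rmn(e)>0)
(Crp AND RpoN)
(NOT(o2(e)>0) AND (tartr-L(e)>0))
(tartr-L(e)>0)
(ArcA OR Fnr AND (Crp OR NOT (NarL)))
(NOT ArgR) OR (arg-L(e)>0)
(NOT PurR)
(NOT (PurR AND Crp))
ON
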