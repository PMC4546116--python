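tissue	regulator	target
cortex	Ifng	Actb
cortex	Ifng	Adipoq
cortex	Ifng	C3
cortex	Ifng	Cdkn1a
cortex	Ifng	Dbp
cortex	Ifng	Hspb1
cortex	Ifng	Nupr1
cortex	Tnf	Actb
cortex	Tnf	Adipoq
cortex	Tnf	C3
cortex	Tnf	Cdkn1a
cortex	Tnf	Cfd
cortex	Tnf	Dcn
cortex	Tnf	Per2
cortex	Cebpb	Adipoq
cortex	Cebpb	C3
cortex	Cebpb	Cdkn1a
cortex	Cebpb	Cfd
cortex	Cebpb	Dcn
cortex	Cebpb	Nupr1
cortex	Il1B	C3
cortex	Il1B	Cdkn1a
cortex	Il1B	Dbp
cortex	Il1B	Dcn
cortex	Il1B	Hspb1
cortex	Il1B	S100a6
cortex	Cebpa	Adipoq
cortex	Cebpa	C3
cortex	Cebpa	Cdkn1a
cortex	Cebpa	Cfd
cortex	Cebpa	Mup1
cortex	Pparg	Adipoq
cortex	Pparg	Cdkn1a
cortex	Pparg	Cfd
cortex	Pparg	Hmgcs2
cortex	Erbb2	Actb
cortex	Erbb2	Cdkn1a
cortex	Erbb2	Hspb1
cortex	Erbb2	S100a6
cortex	Hoxa10	Actb
cortex	Hoxa10	Adipoq
cortex	Hoxa10	Cdkn1a
cortex	Hoxa10	Cfd
cortex	Ins1	Actb
cortex	Ins1	Adipoq
cortex	Ins1	Cdkn1a
cortex	Ins1	Cfd
cortex	Lep	Adipoq
cortex	Lep	Cdkn1a
cortex	Lep	Cfd
cortex	Lep	Per2
cortex	Psen1	Actb
cortex	Psen1	C3
cortex	Psen1	Ckb
cortex	Psen1	Dbp
cortex	Psen1	Nupr1
cortex	NFkB (complex)	C3
cortex	NFkB (complex)	Cdkn1a
cortex	NFkB (complex)	Dbp
cortex	NFkB (complex)	Hspb1
cortex	Hras	Actb
cortex	Hras	Cdkn1a
cortex	Hras	Hspb1
cortex	Edn1	Actb
cortex	Edn1	Adipoq
cortex	Edn1	Nupr1
cortex	Egfr	Actb
cortex	Egfr	Cdkn1a
cortex	Egfr	Hspb1
medulla	Ifng	Actb
medulla	Ifng	C3
medulla	Ifng	Cdkn1a
medulla	Ifng	Dbp
medulla	Ifng	Egr1
medulla	Ifng	Pck1
medulla	Tnf	C3
medulla	Tnf	Cdkn1a
medulla	Tnf	Egr1
medulla	Cebpb	C3
medulla	Cebpb	Cdkn1a
medulla	Il1B	C3
medulla	Il1B	Ccrn4l
medulla	Il1B	Cdkn1a
medulla	Il1B	Dbp
medulla	Il1B	Egr1
medulla	Pparg	Cdkn1a
medulla	Pparg	Hmgcs2
medulla	Pparg	Pck1
medulla	Hoxa10	Actb
medulla	Hoxa10	Cdkn1a
medulla	Lep	Cdkn1a
medulla	Lep	Pck1
medulla	NFkB (complex)	C3
medulla	NFkB (complex)	Cdkn1a
medulla	NFkB (complex)	Dbp
medulla	NFkB (complex)	Egr1
medulla	Hras	Actb
medulla	Hras	Cdkn1a
medulla	Hras	Egr1
medulla	Hras	Pck1
medulla	Edn1	Egr1
medulla	Egfr	Actb
medulla	Egfr	Cdkn1a
medulla	Egfr	Egr1
medulla	Nr3c1	Actb
medulla	Nr3c1	Cdkn1a
medulla	Nr3c1	Hmgcs2
medulla	Nr3c1	Pck1
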