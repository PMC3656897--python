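id	kind	label	signature_34	signature_10
Leu.r0	A	Leu	FFPTCLAPWRECDPKKCTMLCNQAAPGQMPPHGR	FPWEDKMLAG
Leu.r1	A	Leu	FFPTCLAPWQECDPKVCTMSVNQHAPGQMPPHGC	FPWEDKMSAG
Leu.r2	A	Leu	FFPTCLAPWRECDPAVCEMSVNQHAPGQMPPHVR	FPWEDAMSAG
Glu.r0	A	Glu	FGMTNLKPRRECTWHVCTAHVNWPNPSSMRPSEK	GMRETHAHNS
Glu.r1	A	Glu	FYMTNLKPRRECTWHVCTAHVNWPNPMSMVPSEK	YMRETHAHNM
Glu.r2	A	Glu	FGMTNLKIRSEYYWHVCTAHVNWPNPSSMVPSEK	GMREYHAHNS
Gln.r0	A	Gln	FMHTDLTWWRECSTHVHTRSVNAHEGTIMQNSEK	MHWESHRSET
Gln.r1	A	Gln	FMHTDLTWWRECSTHSHTRSVNAHEGTIMQPSEK	MHWESHRSET
Gln.r2	A	Gln	FMHTDLTWWRECSTHVHTRSVNAREGWIMQPSEK	MHWESHRSEW
Val.r0	A	Val	WVYTTLAVTRVCMPFHGTNANNADNPMIMIPSMM	VYTVMFNANM
Val.r1	A	Val	WVYTELAPTRVCMPFHGTHVSNARNPMIMQPSMM	VYTVMFHVNM
Val.r2	A	Val	WVYTELAPTRVCMPFEGTHANNADNPMIMQPSMM	VYTVMFHANM
Ser.r0	A	Ser	FEQTENAPDRNCPPPVNTCRRNAHLPRIGTPHIC	EQDNPPCRLR
Ser.r1	A	Ser	FEGTENAPDRNCPPPVNGWRANAHLPRIGTPHPC	EGDNPPWRLR
Ser.r2	A	Ser	FEQTENAPDRNCPPPVNTWRRNAHLPRIATPHIC	EQDNPPWRLR
Ile.r0	A	Ile	FACQELHPQRPCCPNVKGAMVNAHTPYTMQNSFK	ACQPCNAMTY
Ile.r1	A	Ile	FACQELHPQRPCCPNVKGAMHQAHTNSTMQNSFK	ACQPCNAMTS
Ile.r2	A	Ile	FACQELHEQRPCCPNVKGAMVNAHTPYTMQNSFK	ACQPCNAMTY
Asp.r0	A	Asp	IDQTEMVPNRVCGPQVCTYRVMSHRPSQWHPSEN	DQNVGQYRRS
Asp.r1	A	Asp	IGQTEDVPNRVCGPQACTQRVMSHRPSQHRPSEK	GQNVGQQRRS
Asp.r2	A	Asp	IGQTEMVPNRVCGPQVCTYRVMSHRPSQWHPSEK	GQNVGQYRRS
Thr.r0	A	Thr	FDATELAKTRDCAPTKLTYTVNPHLPYIMQCNED	DATDATYTLY
Thr.r1	A	Thr	FDATELAKTRDCAPTKLTYTVNPHLPYIMQCNEK	DATDATYTLY
Thr.r2	A	Thr	FDATELAKTRVCAPTKNTYTVNPHLPYIMQCNEK	DATVATYTLY
starter.r0	C	starter		
starter.r1	C	starter		
starter.r2	C	starter		
dual.r0	C	dual		
dual.r1	C	dual		
dual.r2	C	dual		
conventional.r0	C	conventional		
conventional.r1	C	conventional		
conventional.r2	C	conventional		
TE1.r0	TE	TE1		
TE1.r1	TE	TE1		
TE1.r2	TE	TE1		
TE2.r0	TE	TE2		
TE2.r1	TE	TE2		
TE2.r2	TE	TE2		
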