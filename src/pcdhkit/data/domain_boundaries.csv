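# EC-domain boundaries (author numbering of the mature ectodomain) for the
# deposited gamma-protocadherin ectodomain fragment entries and the published
# alpha/beta/gammaB comparison entries.
#
# APPROXIMATE: intervals follow the ~100-residue cadherin EC-domain
# periodicity anchored on residue numbers quoted for these structures
# (e.g. E41 in EC1, 111 in EC2, 294 in EC3, 338/340 in EC4, the EC6 A strand
# at 531-532 and G-strand O-mannose sites 624-628).  The accession-to-
# construct mapping follows the deposition order of the entries; verify both
# against the fetched depositions before production use and edit as needed.
#
# construct: 5szl=gA1_EC1-4  5szm=gA8_EC1-4  5szn=gA9_EC1-5  5szo=gB2_EC1-5
#            5szp=gB7_EC1-4 form1  5szq=gB7_EC1-4 form2
#            5szr=gA4_EC3-6  5t9t=gB2_EC3-6
#            5dzw=a4_EC1-4  5dzv=a7_EC1-5  5dzx=b6_EC1-4  5dzy=b8_EC1-4
#            5k8r=gB3_EC1-4
pdb_id,chain,domain,start,end
5szl,A,EC1,1,103
5szl,A,EC2,104,213
5szl,A,EC3,214,314
5szl,A,EC4,315,424
5szl,B,EC1,1,103
5szl,B,EC2,104,213
5szl,B,EC3,214,314
5szl,B,EC4,315,424
5szl,C,EC1,1,103
5szl,C,EC2,104,213
5szl,C,EC3,214,314
5szl,C,EC4,315,424
5szl,D,EC1,1,103
5szl,D,EC2,104,213
5szl,D,EC3,214,314
5szl,D,EC4,315,424
5szm,A,EC1,1,103
5szm,A,EC2,104,213
5szm,A,EC3,214,314
5szm,A,EC4,315,424
5szn,A,EC1,1,103
5szn,A,EC2,104,213
5szn,A,EC3,214,314
5szn,A,EC4,315,424
5szn,A,EC5,425,527
5szo,A,EC1,1,103
5szo,A,EC2,104,213
5szo,A,EC3,214,314
5szo,A,EC4,315,424
5szo,A,EC5,425,527
5szo,B,EC1,1,103
5szo,B,EC2,104,213
5szo,B,EC3,214,314
5szo,B,EC4,315,424
5szo,B,EC5,425,527
5szp,A,EC1,1,103
5szp,A,EC2,104,213
5szp,A,EC3,214,314
5szp,A,EC4,315,424
5szp,B,EC1,1,103
5szp,B,EC2,104,213
5szp,B,EC3,214,314
5szp,B,EC4,315,424
5szq,A,EC1,1,103
5szq,A,EC2,104,213
5szq,A,EC3,214,314
5szq,A,EC4,315,424
5szq,B,EC1,1,103
5szq,B,EC2,104,213
5szq,B,EC3,214,314
5szq,B,EC4,315,424
5szr,A,EC3,214,314
5szr,A,EC4,315,424
5szr,A,EC5,425,527
5szr,A,EC6,528,628
5t9t,A,EC3,214,314
5t9t,A,EC4,315,424
5t9t,A,EC5,425,527
5t9t,A,EC6,528,628
5dzw,A,EC1,1,103
5dzw,A,EC2,104,213
5dzw,A,EC3,214,314
5dzw,A,EC4,315,424
5dzw,B,EC1,1,103
5dzw,B,EC2,104,213
5dzw,B,EC3,214,314
5dzw,B,EC4,315,424
5dzv,A,EC1,1,103
5dzv,A,EC2,104,213
5dzv,A,EC3,214,314
5dzv,A,EC4,315,424
5dzv,A,EC5,425,527
5dzv,B,EC1,1,103
5dzv,B,EC2,104,213
5dzv,B,EC3,214,314
5dzv,B,EC4,315,424
5dzv,B,EC5,425,527
5dzx,A,EC1,1,103
5dzx,A,EC2,104,213
5dzx,A,EC3,214,314
5dzx,A,EC4,315,424
5dzx,B,EC1,1,103
5dzx,B,EC2,104,213
5dzx,B,EC3,214,314
5dzx,B,EC4,315,424
5dzy,A,EC1,1,103
5dzy,A,EC2,104,213
5dzy,A,EC3,214,314
5dzy,A,EC4,315,424
5dzy,B,EC1,1,103
5dzy,B,EC2,104,213
5dzy,B,EC3,214,314
5dzy,B,EC4,315,424
5k8r,A,EC1,1,103
5k8r,A,EC2,104,213
5k8r,A,EC3,214,314
5k8r,A,EC4,315,424
5k8r,B,EC1,1,103
5k8r,B,EC2,104,213
5k8r,B,EC3,214,314
5k8r,B,EC4,315,424
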