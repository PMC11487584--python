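# Frequency of tissue-composition categories over the 118 ROIs with an
# assessable CT scan (3 further ROIs lacked a usable CT and are omitted).
# 'category' distinguishes regular (ST) from swollen (SST) subcutaneous
# tissue; 'no_bone' marks compositions without cranial bone (printed with a
# trailing asterisk in the source table; the marker is not part of the
# composition grammar).
category,composition,count,no_bone
regular,ST+CB+NB,14,False
regular,ST+CB+CSF/NB,7,False
regular,ST+CB+A/CSF+NB,3,False
regular,ST+CB+CSF+NB,22,False
regular,ST+CB+A+NB,2,False
regular,ST+CB+A+BC,1,False
regular,ST+CB+BC,2,False
regular,ST+CB+SAH+BC,2,False
regular,ST+CB+SAH+NB,6,False
regular,ST+CB+ICH/NB,1,False
regular,ST+CB+IT,4,False
regular,ST+A+NB,1,True
regular,ST+EH+BC,1,True
regular,ST+EH+IT,3,True
regular,ST+EH+CSF/IT,2,True
regular,ST+IT/NB,1,True
swollen,SST+CB+NB,13,False
swollen,SST+CB+CSF/NB,2,False
swollen,SST+CB+CSF/A+NB,1,False
swollen,SST+CB+CSF+NB,10,False
swollen,SST+CB+A+NB,5,False
swollen,SST+CB/A+NB,1,False
swollen,SST+CB+BC,2,False
swollen,SST+CB+CSF/SAH+NB,3,False
swollen,SST+CB+EH+CSF,1,False
swollen,SST+CB+EH+CSF+NB,1,False
swollen,SST+CB,2,False
swollen,SST+CB+EH,1,False
swollen,SST+CSF+CB/A,1,False
swollen,SST+EH+IT,1,True
swollen,SST+CSF+NB,1,True
swollen,SST+IT,1,True
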