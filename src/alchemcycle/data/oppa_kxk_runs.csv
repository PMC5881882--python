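environment,pair_from,pair_to,direction,replicate,executed_from,executed_to,value,uncertainty,sign_corrected
solvent,A,G,forward,s1,A,G,-3.9,0.4,False
solvent,A,G,backward,s1,G,A,4.2,0.4,False
solvent,G,S,forward,s1,G,S,-22.5,0.5,False
solvent,G,S,backward,s1,S,G,22.4,0.5,False
solvent,A,S,forward,s1,A,S,-26.2,0.4,False
solvent,A,S,backward,s1,S,A,26.3,0.4,False
bound,A,G,forward,b1,A,G,6.8,0.7,False
bound,A,G,backward,b1,G,A,-1.6,1.0,False
bound,A,G,forward,b2,G,A,-4.1,1.1,False
bound,A,G,backward,b2,A,G,5.4,0.9,False
bound,G,S,forward,b1,G,S,-31.6,1.9,False
bound,G,S,backward,b1,S,G,37.4,1.7,False
bound,G,S,forward,b2,S,G,-35.7,2.2,True
bound,G,S,backward,b2,G,S,-33.8,2.0,False
bound,A,S,forward,b1,A,S,-30.2,1.7,False
bound,A,S,backward,b1,S,A,32.4,2.0,False
bound,A,S,forward,b2,S,A,33.5,1.9,False
bound,A,S,backward,b2,A,S,-33.9,1.4,False
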